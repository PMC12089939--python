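"""Gene-level evidence ranking and rank fusion.

Gene-based association methods (positional GWAS aggregation, TWAS/SMR
expression approaches, rare-variant burden masks) each emit one p-value
per gene, over partially overlapping gene universes.  This module turns
each method's p-values into ascending ranks (rank 1 = strongest
evidence), fuses the per-gene ranks into *raw median* and *scaled
median* summaries, and provides dispersion (coefficient of variation)
and cross-evidence correlation diagnostics.

The scaled median is the raw median divided by the number of
non-missing input ranks, which up-weights genes supported by several
independent lines of evidence.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PVAL_COLUMNS = ("gene_id", "method_id", "p_value")
EVIDENCE_CLASSES = ("common", "rare")
TIE_RULES = ("average", "ordinal")
REWEIGHT_SCHEMES = ("coloc_weight", "heidi_demote")

#: minimum number of input ranks for the coefficient of variation
CV_MIN_INPUTS = 5


def normalize_gene_ids(ids: pd.Series) -> pd.Series:
    """Upper-case and strip gene symbols so evidence streams join cleanly."""
    return ids.astype(str).str.strip().str.upper()


def validate_pval_table(pvals: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a per-method gene p-value table.

    Requires columns ``gene_id``, ``method_id``, ``p_value`` (an
    ``evidence_class`` column is carried through when present).  Raises
    ``ValueError`` on duplicate (gene, method) pairs or p-values outside
    (0, 1].
    """
    missing = [c for c in PVAL_COLUMNS if c not in pvals.columns]
    if missing:
        raise ValueError(f"p-value table lacks required columns: {missing}")
    if len(pvals) == 0:
        raise ValueError("p-value table is empty; at least one method required")
    out = pvals.copy()
    out["gene_id"] = normalize_gene_ids(out["gene_id"])
    out["method_id"] = out["method_id"].astype(str)
    p = out["p_value"].to_numpy(dtype=float)
    bad = ~((p > 0.0) & (p <= 1.0))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"p_value outside (0,1]: {p[i]!r} for gene "
            f"{out['gene_id'].iloc[i]!r}, method {out['method_id'].iloc[i]!r}"
        )
    dup = out.duplicated(subset=["gene_id", "method_id"])
    if dup.any():
        row = out.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (gene, method) pair: ({row['gene_id']!r}, {row['method_id']!r})"
        )
    return out


def rank_genes(pvals: pd.DataFrame, tie_rule: str = "average") -> pd.DataFrame:
    """Rank genes per method by ascending p-value (rank 1 = smallest p).

    ``tie_rule='average'`` assigns tied p-values their average rank
    (ranks may be non-integer); ``'ordinal'`` breaks ties by gene
    symbol, giving an exact permutation of 1..n per method.  Genes
    absent from a method simply have no row for that method.

    Returns a long-format RankMatrix with columns ``gene_id``,
    ``method_id``, ``rank``.
    """
    if tie_rule not in TIE_RULES:
        raise ValueError(f"unknown tie_rule {tie_rule!r}; expected one of {TIE_RULES}")
    table = validate_pval_table(pvals)
    if tie_rule == "average":
        table["rank"] = table.groupby("method_id")["p_value"].rank(method="average")
    else:
        table = table.sort_values(["method_id", "p_value", "gene_id"], kind="stable")
        table["rank"] = table.groupby("method_id")["p_value"].rank(method="first")
    cols = ["gene_id", "method_id", "rank"]
    if "evidence_class" in table.columns:
        cols.append("evidence_class")
    return table[cols].reset_index(drop=True)


def coefficient_of_variation(
    ranks_for_gene: Sequence[float], min_inputs: int = CV_MIN_INPUTS
) -> float | None:
    """Dispersion of a gene's input ranks: sample sd (n-1) over mean.

    Returns ``None`` (absent, not an error) when fewer than
    ``min_inputs`` ranks are supplied — a CV over very few ranks is not
    a meaningful stability diagnostic.
    """
    v = np.asarray(list(ranks_for_gene), dtype=float)
    if v.size < min_inputs:
        return None
    return float(v.std(ddof=1) / v.mean())


def fuse_ranks(ranks: pd.DataFrame) -> pd.DataFrame:
    """Fuse a RankMatrix into per-gene raw/scaled median summaries.

    Missing (gene, method) entries are ignored: the raw median is taken
    over the n available ranks (a single available rank is reported
    as-is), and the scaled median divides by n so that multi-evidence
    genes are favoured.  Genes with no ranks at all do not appear.

    Returns columns ``gene_id``, ``raw_median``, ``n_nonmissing``,
    ``scaled_median``, ``coefficient_of_variation`` (NaN below
    ``CV_MIN_INPUTS`` inputs).
    """
    if len(ranks) == 0:
        raise ValueError("rank matrix is empty")
    grouped = ranks.groupby("gene_id")["rank"]
    out = grouped.agg(raw_median="median", n_nonmissing="count").reset_index()
    out["scaled_median"] = out["raw_median"] / out["n_nonmissing"]
    sd = grouped.std(ddof=1)
    mean = grouped.mean()
    cv = (sd / mean).where(grouped.count() >= CV_MIN_INPUTS)
    out["coefficient_of_variation"] = out["gene_id"].map(cv).astype(float)
    return out


def reweight_expression_ranks(
    assoc: pd.DataFrame,
    evidence: pd.Series | dict,
    scheme: str = "coloc_weight",
    heidi_threshold: float = 0.05,
    method_suffix: str | None = None,
) -> pd.DataFrame:
    """Derive a colocalization/HEIDI-adjusted evidence stream from TWAS/SMR p-values.

    Expression-based associations can reflect linkage rather than a
    shared causal variant; these schemes demote genes whose signal
    colocalization evidence contradicts.

    ``coloc_weight``: score = -log10(p) x posterior (posterior in
    [0, 1]); genes are re-ordered by descending score, so a near-zero
    posterior demotes even a top TWAS gene.
    ``heidi_demote``: genes with HEIDI p below ``heidi_threshold``
    (heterogeneity, i.e. likely linkage) are ordered after all passing
    genes; within-group order follows the raw p-values.

    Genes with no evidence value keep their raw standing (posterior 1 /
    HEIDI pass) and are flagged ``adjusted=False``.  The result is a
    p-value table (order encoded as pseudo p-values ``i/(n+1)``) usable
    as an additional method column in :func:`rank_genes`.
    """
    if scheme not in REWEIGHT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {REWEIGHT_SCHEMES}")
    table = validate_pval_table(assoc)
    ev = pd.Series(evidence, dtype=float)
    ev.index = normalize_gene_ids(pd.Series(ev.index))
    suffix = method_suffix if method_suffix is not None else scheme
    out_frames = []
    for method_id, grp in table.groupby("method_id", sort=True):
        grp = grp.copy()
        grp["evidence"] = grp["gene_id"].map(ev)
        grp["adjusted"] = grp["evidence"].notna()
        if scheme == "coloc_weight":
            post = grp["evidence"].to_numpy(dtype=float)
            known = ~np.isnan(post)
            if ((post[known] < 0) | (post[known] > 1)).any():
                raise ValueError("colocalization posterior outside [0, 1]")
            post = np.where(known, post, 1.0)
            grp["score"] = -np.log10(grp["p_value"].to_numpy()) * post
            grp = grp.sort_values(
                ["score", "p_value", "gene_id"],
                ascending=[False, True, True],
                kind="stable",
            )
        else:  # heidi_demote
            fails = grp["evidence"] < heidi_threshold  # NaN -> False: treated as pass
            grp["demoted"] = fails
            grp = grp.sort_values(
                ["demoted", "p_value", "gene_id"], kind="stable"
            )
        n = len(grp)
        grp["p_value"] = np.arange(1, n + 1) / (n + 1)
        grp["method_id"] = f"{method_id}_{suffix}"
        cols = ["gene_id", "method_id", "p_value", "adjusted"]
        if "evidence_class" in grp.columns:
            cols.append("evidence_class")
        out_frames.append(grp[cols])
    return pd.concat(out_frames, ignore_index=True)


def correlate_rank_vectors(
    a: pd.DataFrame, b: pd.DataFrame, column: str = "scaled_median"
) -> tuple[float, float]:
    """Spearman's rho between two rank summaries over their shared genes.

    Rank-based, so it is insensitive to the monotone difference between
    raw and scaled medians.  Requires at least 3 shared genes.
    """
    merged = a[["gene_id", column]].merge(
        b[["gene_id", column]], on="gene_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared genes; need at least 3 for Spearman's rho"
        )
    rho, p = stats.spearmanr(merged[f"{column}_a"], merged[f"{column}_b"])
    return float(rho), float(p)


def read_pval_table(path) -> pd.DataFrame:
    """Read a tab-separated gene/method/p-value table and validate it."""
    return validate_pval_table(pd.read_csv(path, sep="\t"))


def write_rank_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)
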