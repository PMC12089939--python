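"""From-scratch preranked gene-set enrichment (GSEA-style).

Given a ranked gene list and a collection of gene sets, computes the
weighted running-sum enrichment score (ES), a gene-shuffle permutation
null, the normalized enrichment score (NES = ES divided by the mean
same-sign permuted ES), one-sided empirical p-values, per-tail FDR q
values (GSEA ratio method), permutation-max FWER and Bonferroni.

Orientation matters here.  The scores in this pipeline are median rank
values (1 = best gene), and the list is scored in *descending* score
order, so the best genes sit at the bottom of the list: a gene set
enriched among the best-ranked genes therefore attains a **negative**
ES/NES.  This deliberately replicates the orientation used to interpret
drug-class enrichments, where NES < 0 flags a candidate class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geneset_io import GeneSet, GeneSetCollection

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500
DEFAULT_WEIGHT = 1.0


@dataclass
class RankedArrays:
    """A ranked list prepared for scoring: genes sorted by descending score."""

    genes: np.ndarray        # sorted gene symbols
    scores: np.ndarray       # scores in list order (descending)
    weights: np.ndarray      # |score| ** weight_exponent, list order
    index: dict              # gene -> position


def prepare_ranked(ranked: pd.DataFrame, weight_exponent: float = DEFAULT_WEIGHT) -> RankedArrays:
    """Sort a (gene_id, score) frame by descending score, ties stably by gene_id.

    The stable gene-symbol tie-break makes runs byte-reproducible even
    when many genes share a median rank value.
    """
    if ranked["gene_id"].duplicated().any():
        dup = ranked.loc[ranked["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene in ranked list: {dup!r}")
    df = ranked.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    )
    genes = df["gene_id"].to_numpy(dtype=object)
    scores = df["score"].to_numpy(dtype=float)
    weights = np.abs(scores) ** weight_exponent
    return RankedArrays(
        genes=genes,
        scores=scores,
        weights=weights,
        index={g: i for i, g in enumerate(genes)},
    )


def filter_sets(
    collection: GeneSetCollection,
    ranked: RankedArrays | pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Keep sets whose intersection with the ranked universe has min..max members.

    Members outside the universe are dropped *before* the size test, so
    a 10-member set with only 4 genes in the universe is excluded.
    """
    universe = (
        set(ranked.index) if isinstance(ranked, RankedArrays) else set(ranked["gene_id"])
    )
    kept = GeneSetCollection()
    for gene_set in collection:
        inter = tuple(g for g in gene_set.members if g in universe)
        if min_size <= len(inter) <= max_size:
            kept.add(GeneSet(gene_set.set_id, gene_set.description, inter))
    return kept


def _running_sum(ranked: RankedArrays, positions: np.ndarray) -> np.ndarray:
    """Full running-sum profile over the list for a set at given positions."""
    n = len(ranked.genes)
    k = len(positions)
    if k == 0 or k >= n:
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    hit_w = ranked.weights[positions]
    total = hit_w.sum()
    steps = np.full(n, -1.0 / (n - k))
    if total > 0:
        steps[positions] = hit_w / total
    else:  # all-zero scores at the hits: fall back to unweighted hits
        steps[positions] = 1.0 / k
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedArrays,
    set_members,
    weight_exponent: float | None = None,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov–Smirnov-like enrichment score for one gene set.

    Walking the descending-sorted list, hits increment the running sum
    by |score|^p (normalized over hits) and misses decrement by
    1/(N - |S|); the ES is the maximum-magnitude deviation.  The leading
    edge contains the members at or before the extremum for positive ES,
    at or after it for negative ES.

    ``weight_exponent`` other than the one used in :func:`prepare_ranked`
    recomputes hit weights on the fly.

    Returns ``(es, running_sum, leading_edge)``.
    """
    if weight_exponent is not None:
        ranked = RankedArrays(
            genes=ranked.genes,
            scores=ranked.scores,
            weights=np.abs(ranked.scores) ** weight_exponent,
            index=ranked.index,
        )
    positions = np.sort(
        np.array([ranked.index[g] for g in set_members if g in ranked.index], dtype=np.int64)
    )
    if len(positions) == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    profile = _running_sum(ranked, positions)
    peak = int(np.argmax(np.abs(profile)))
    es = float(profile[peak])
    if es >= 0:
        edge_pos = positions[positions <= peak]
    else:
        edge_pos = positions[positions >= peak]
    leading_edge = [str(g) for g in ranked.genes[edge_pos]]
    return es, profile, leading_edge


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many position subsets (rows of ``positions``).

    Uses the fact that the running sum only attains candidate extrema
    just before and just after each hit: between hits it decays
    linearly.  O(k log k) per subset instead of O(N).
    """
    positions = np.sort(positions, axis=1)
    n_sub, k = positions.shape
    hit_w = weights[positions].astype(float)
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] <= 0
    if zero.any():
        hit_w[zero] = 1.0
        totals = hit_w.sum(axis=1, keepdims=True)
    cum = np.cumsum(hit_w, axis=1) / totals
    miss = (positions - np.arange(k)) / (n - k)
    after = cum - miss          # value just after each hit (list index = position)
    before = after - hit_w / totals  # value just before each hit (index = position - 1)
    rows = np.arange(n_sub)
    i_pos = after.argmax(axis=1)
    i_neg = before.argmin(axis=1)
    es_pos = after[rows, i_pos]
    es_neg = before[rows, i_neg]
    idx_pos = positions[rows, i_pos]
    idx_neg = positions[rows, i_neg] - 1
    # ES = running-sum value of maximum magnitude; exact-magnitude ties go to
    # whichever extremum occurs first along the list (matches the full profile)
    take_pos = (np.abs(es_pos) > np.abs(es_neg)) | (
        (np.abs(es_pos) == np.abs(es_neg)) & (idx_pos <= idx_neg)
    )
    return np.where(take_pos, es_pos, es_neg)


def permutation_null(
    ranked: RankedArrays,
    set_sizes,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Gene-shuffle null: ES of uniformly random subsets of each requested size.

    A random-subset null is the appropriate permutation scheme for
    preranked input (there are no phenotype labels to shuffle).  Sets of
    equal size share one null sample.  The seed is mandatory for
    reproducibility.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ranked.genes)
    null: dict[int, np.ndarray] = {}
    for size in sorted(set(int(s) for s in set_sizes)):
        if size >= n:
            raise ValueError(f"set size {size} is not smaller than the universe ({n})")
        positions = np.empty((n_perm, size), dtype=np.int64)
        for j in range(n_perm):
            positions[j] = rng.choice(n, size=size, replace=False)
        null[size] = _es_from_positions(ranked.weights, positions, n)
    return null


def _same_sign_means(null_es: np.ndarray) -> tuple[float, float]:
    """Mean positive null ES and mean |negative null ES| (NaN when empty)."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    pos_mean = float(pos.mean()) if pos.size else float("nan")
    neg_mean = float(np.abs(neg).mean()) if neg.size else float("nan")
    return pos_mean, neg_mean


def _normalize(es: np.ndarray, pos_mean: float, neg_mean: float) -> np.ndarray:
    """NES: divide by the mean same-sign null ES magnitude, preserving sign."""
    out = np.full_like(np.asarray(es, dtype=float), np.nan)
    es = np.asarray(es, dtype=float)
    if np.isfinite(pos_mean):
        out = np.where(es >= 0, es / pos_mean, out)
    if np.isfinite(neg_mean):
        out = np.where(es < 0, es / neg_mean, out)
    return out


def normalize_and_test(
    es_observed: dict[str, float],
    set_sizes: dict[str, int],
    null: dict[int, np.ndarray],
    n_perm: int,
) -> pd.DataFrame:
    """NES, empirical p, per-tail FDR q, permutation-max FWER and Bonferroni.

    * empirical p: one-sided exceedance among same-sign null ES; when no
      permutation is as extreme, the value ``1/(2*n_perm)`` is reported
      and flagged ``p_below_floor`` (the resolvable floor is 1/n_perm).
    * FDR q (ratio method, per tail): the share of pooled same-sign null
      NES at least as extreme, divided by the share of observed
      same-sign NES at least as extreme, clipped to [0, 1].
    * FWER: exceedance of the per-permutation most-extreme same-sign NES
      across all tested sets; Bonferroni = min(1, p * n_sets) is also
      reported.
    """
    set_ids = list(es_observed)
    if not set_ids:
        raise ValueError("no observed enrichment scores supplied")
    for size in set(set_sizes.values()):
        if size not in null or len(null[size]) == 0:
            raise ValueError(f"empty permutation null for set size {size}")

    means = {size: _same_sign_means(null[size]) for size in null}
    # per-set null NES (normalized by that set's same-sign null means)
    null_nes = {}
    for sid in set_ids:
        pos_mean, neg_mean = means[set_sizes[sid]]
        null_nes[sid] = _normalize(null[set_sizes[sid]], pos_mean, neg_mean)

    rows = []
    nes_obs = {}
    for sid in set_ids:
        es = es_observed[sid]
        null_es = null[set_sizes[sid]]
        pos_mean, neg_mean = means[set_sizes[sid]]
        if es >= 0:
            same = null_es[null_es > 0]
            exceed = int((same >= es).sum())
            nes = es / pos_mean if np.isfinite(pos_mean) else float("nan")
        else:
            same = null_es[null_es < 0]
            exceed = int((same <= es).sum())
            nes = es / neg_mean if np.isfinite(neg_mean) else float("nan")
        below_floor = exceed == 0
        denom = max(len(same), 1)
        p_emp = (exceed / denom) if exceed else 1.0 / (2 * n_perm)
        nes_obs[sid] = nes
        rows.append((sid, es, nes, p_emp, below_floor))

    obs = np.array([nes_obs[sid] for sid in set_ids], dtype=float)
    pooled = np.concatenate([null_nes[sid] for sid in set_ids])
    pooled_pos = pooled[pooled > 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = obs[np.isfinite(obs) & (obs > 0)]
    obs_neg = obs[np.isfinite(obs) & (obs < 0)]

    # per-permutation most extreme same-sign NES across sets, for FWER
    nes_matrix = np.vstack([null_nes[sid] for sid in set_ids])
    with np.errstate(invalid="ignore"):
        pos_matrix = np.where(np.isfinite(nes_matrix) & (nes_matrix > 0), nes_matrix, -np.inf)
        neg_matrix = np.where(np.isfinite(nes_matrix) & (nes_matrix < 0), nes_matrix, np.inf)
    max_pos = pos_matrix.max(axis=0)
    min_neg = neg_matrix.min(axis=0)

    n_sets = len(set_ids)
    records = []
    for sid, es, nes, p_emp, below_floor in rows:
        if not np.isfinite(nes):
            fdr = float("nan")
            fwer = float("nan")
        elif nes >= 0:
            num = (pooled_pos >= nes).mean() if pooled_pos.size else 0.0
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
            fdr = min(1.0, num / den) if den > 0 else 0.0
            fwer = float((max_pos >= nes).mean())
        else:
            num = (pooled_neg <= nes).mean() if pooled_neg.size else 0.0
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
            fdr = min(1.0, num / den) if den > 0 else 0.0
            fwer = float((min_neg <= nes).mean())
        records.append(
            {
                "set_id": sid,
                "es": es,
                "nes": nes,
                "p": p_emp,
                "p_below_floor": below_floor,
                "fdr_q": fdr,
                "fwer_p": fwer,
                "fwer_bonferroni": min(1.0, p_emp * n_sets),
            }
        )
    return pd.DataFrame(records)


def assign_tier(fdr_q: float, fwer_p: float, threshold: float = 0.05) -> str:
    """Evidence tier: 'strong' when FDR and FWER < threshold, 'moderate' when one is."""
    hits = int(fdr_q < threshold) + int(fwer_p < threshold)
    return {2: "strong", 1: "moderate", 0: ""}[hits]


def run_enrichment(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    weight_exponent: float = DEFAULT_WEIGHT,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    seed: int | np.random.Generator | None = None,
    tier_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full preranked enrichment of a gene-set collection against a ranked list.

    ``ranked`` is a (gene_id, score) frame — for this pipeline the score
    is the raw or scaled median rank, so NES < 0 marks sets enriched for
    the best-ranked genes.  Results are sorted by NES ascending (most
    negative, i.e. most interesting, first).
    """
    arrays = prepare_ranked(ranked, weight_exponent)
    kept = filter_sets(collection, arrays, min_size, max_size)
    if len(kept) == 0:
        import warnings

        warnings.warn("no gene sets survive the size filter", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "set_id", "size", "es", "nes", "p", "p_below_floor",
                "fdr_q", "fwer_p", "fwer_bonferroni", "tier", "leading_edge",
            ]
        )
    es_observed: dict[str, float] = {}
    sizes: dict[str, int] = {}
    edges: dict[str, list[str]] = {}
    for gene_set in kept:
        es, _, edge = enrichment_score(arrays, gene_set.members)
        es_observed[gene_set.set_id] = es
        sizes[gene_set.set_id] = len(gene_set)
        edges[gene_set.set_id] = edge
    null = permutation_null(arrays, sizes.values(), n_perm=n_perm, seed=seed)
    results = normalize_and_test(es_observed, sizes, null, n_perm)
    results.insert(1, "size", results["set_id"].map(sizes))
    results["tier"] = [
        assign_tier(q, f, tier_threshold)
        for q, f in zip(results["fdr_q"], results["fwer_p"])
    ]
    results["leading_edge"] = results["set_id"].map(
        lambda sid: ",".join(edges[sid])
    )
    return results.sort_values(["nes", "set_id"], kind="stable").reset_index(drop=True)


def compare_nes_vectors(
    a: pd.DataFrame, b: pd.DataFrame, column: str = "nes"
) -> tuple[float, float]:
    """Kendall's tau-b between two enrichment results over shared set_ids.

    Tau-b handles the extensive ties typical of NES vectors over small
    collections; requires at least 3 shared sets.
    """
    merged = a[["set_id", column]].merge(
        b[["set_id", column]], on="set_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared gene sets; need at least 3 for Kendall's tau"
        )
    tau, p = stats.kendalltau(merged[f"{column}_a"], merged[f"{column}_b"])
    return float(tau), float(p)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
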