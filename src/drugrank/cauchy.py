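"""Cauchy-combination (ACAT) aggregation of transcript burden p-values.

Rare-variant burden tests are run per transcript and annotation mask;
a gene-level p-value per mask is obtained by the Cauchy combination
test: each p-value is mapped to a standard Cauchy quantile,
``tan(pi * (0.5 - p))``, and the (weighted) mean of these quantiles is
itself approximately standard Cauchy under the null *regardless of the
dependence* among the inputs — which is what makes the statistic robust
to the strong covariance between overlapping transcripts of one gene.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

#: clamp for input p-values; beyond this the tangent overflows double precision
P_CLAMP = 1e-15

#: above this Cauchy statistic the arctan loses precision; use the 1/(pi*T) tail
_TAIL_STAT = 1e10

#: the eight rare-variant annotation masks that are ranked downstream
RARE_MASKS = (
    "disruptive_maf0.01",
    "disruptive_maf0.005",
    "damaging_maf0.01",
    "damaging_maf0.005",
    "disruptive_damaging_maf0.01",
    "disruptive_damaging_maf0.005",
    "disruptive_damaging_missense_maf0.01",
    "disruptive_damaging_missense_maf0.005",
)

#: synonymous variation is aggregated for comparison but never ranked
DIAGNOSTIC_MASKS = ("synonymous", "synonymous_maf0.01", "synonymous_maf0.005")

KNOWN_MASKS = RARE_MASKS + DIAGNOSTIC_MASKS


def cauchy_combine(
    p_values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Combine p-values via the Cauchy combination test.

    T = sum(w_i * tan(pi*(0.5 - p_i))) / sum(w_i); the combined p-value
    is ``0.5 - arctan(T)/pi``.  Weights default to equal.  A single
    input is returned unchanged (up to the clamp); the combination is
    driven by the smallest inputs.

    Inputs are clamped to ``[1e-15, 1 - 1e-15]``; for very large T the
    numerically stable Cauchy tail ``1/(pi*T)`` is used instead of the
    arctan form.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights and p-values must have the same length")
        if (w <= 0).any() or np.isnan(w).any():
            raise ValueError("weights must be positive")
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    t = float(np.sum(w * np.tan(np.pi * (0.5 - p))) / np.sum(w))
    if t > _TAIL_STAT:
        return 1.0 / (np.pi * t)
    combined = 0.5 - np.arctan(t) / np.pi
    return float(min(max(combined, P_CLAMP), 1.0 - P_CLAMP))


def validate_transcript_table(transcripts: pd.DataFrame, strict_masks: bool = True) -> pd.DataFrame:
    """Validate a transcript-level burden p-value table.

    Requires columns ``gene_id``, ``mask_id``, ``transcript_id``,
    ``p_value``; an optional ``weight`` column (default 1) is honoured.
    """
    required = ("gene_id", "mask_id", "transcript_id", "p_value")
    missing = [c for c in required if c not in transcripts.columns]
    if missing:
        raise ValueError(f"transcript table lacks required columns: {missing}")
    if len(transcripts) == 0:
        raise ValueError("transcript table is empty")
    out = transcripts.copy()
    out["gene_id"] = out["gene_id"].astype(str).str.strip().str.upper()
    if strict_masks:
        unknown = sorted(set(out["mask_id"]) - set(KNOWN_MASKS))
        if unknown:
            raise ValueError(
                f"unknown mask_id label(s) {unknown}; recognized masks are {list(KNOWN_MASKS)}"
            )
    p = out["p_value"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("transcript p-values must lie in (0, 1]")
    if "weight" not in out.columns:
        out["weight"] = 1.0
    if (out["weight"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("transcript weights must be positive")
    return out


def aggregate_gene_pvals(
    transcripts: pd.DataFrame,
    include_diagnostic: bool = False,
    strict_masks: bool = True,
) -> pd.DataFrame:
    """Aggregate transcript p-values into one gene-level p per (gene, mask).

    Returns a p-value table (columns ``gene_id``, ``method_id``,
    ``p_value``, ``evidence_class``='rare') ready for
    :func:`drugrank.rank_engine.rank_genes`; the synonymous diagnostic
    masks are excluded unless ``include_diagnostic``.
    """
    table = validate_transcript_table(transcripts, strict_masks=strict_masks)
    rows = []
    for (gene, mask), grp in table.groupby(["gene_id", "mask_id"], sort=True):
        if not include_diagnostic and mask in DIAGNOSTIC_MASKS:
            continue
        combined = cauchy_combine(
            grp["p_value"].to_numpy(), grp["weight"].to_numpy()
        )
        rows.append((gene, mask, combined, "rare"))
    return pd.DataFrame(
        rows, columns=["gene_id", "method_id", "p_value", "evidence_class"]
    )


def read_transcript_table(path, strict_masks: bool = True) -> pd.DataFrame:
    return validate_transcript_table(pd.read_csv(path, sep="\t"), strict_masks=strict_masks)
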