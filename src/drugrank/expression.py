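"""Transcriptomic (iPSMN-style) differential-expression adapter.

Differential-expression tables from induced pluripotent stem
cell-derived motor neuron (iPSMN) lines — one per genetic background
(e.g. C9orf72, SOD1, TARDBP, FUS, sporadic, pan-ALS) — are converted to
ranked lists by p-value significance and pushed through the same
preranked enrichment engine as the genetic arm, with identical
parameters and orientation (NES < 0 = enrichment among the most
significantly perturbed genes).
"""

from __future__ import annotations

import pandas as pd

from . import enrichment
from .geneset_io import GeneSetCollection

DE_COLUMNS = ("gene_id", "log_fold_change", "p_value", "background_label")


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"differential-expression table lacks columns: {missing}")
    out = de.copy()
    out["gene_id"] = out["gene_id"].astype(str).str.strip().str.upper()
    p = out["p_value"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("differential-expression p-values must lie in (0, 1]")
    if out.duplicated(subset=["gene_id", "background_label"]).any():
        raise ValueError("duplicate gene within one background")
    return out


def rank_de_genes(de: pd.DataFrame, background: str) -> pd.DataFrame:
    """Rank one background's genes by ascending p (rank 1 = most significant).

    The score is the rank value itself — the same orientation as the
    genetic pipeline, so negative ES flags sets enriched among the most
    significant genes.  Ties are average-ranked.  Fold change is not
    used for ordering (significance-only ranking); it is available in
    the input for reporting.
    """
    table = validate_de_table(de)
    available = sorted(table["background_label"].unique())
    if background not in available:
        raise ValueError(
            f"unknown background {background!r}; available: {available}"
        )
    sub = table[table["background_label"] == background].copy()
    sub["score"] = sub["p_value"].rank(method="average")
    return sub[["gene_id", "score"]].reset_index(drop=True)


def run_background_enrichments(
    de: pd.DataFrame,
    collection: GeneSetCollection,
    backgrounds: list[str] | None = None,
    **params,
) -> dict[str, pd.DataFrame]:
    """Run the enrichment engine once per genetic background.

    ``params`` are forwarded unchanged to
    :func:`drugrank.enrichment.run_enrichment` so the transcriptomic arm
    uses exactly the same algorithmic parameters as the genetic arm.
    """
    table = validate_de_table(de)
    if backgrounds is None:
        backgrounds = sorted(table["background_label"].unique())
    return {
        bg: enrichment.run_enrichment(rank_de_genes(table, bg), collection, **params)
        for bg in backgrounds
    }
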