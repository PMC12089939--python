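"""End-to-end orchestration of the genetic and transcriptomic arms.

The genetic arm ranks genes per method (common-variant methods
directly; rare-variant masks after Cauchy aggregation of transcript
p-values), fuses ranks into raw and scaled medians, and runs preranked
enrichment of ATC level 2/3/4 and mechanism-of-action gene sets against
all four ranked lists (2 evidence classes x 2 median variants), plus
Kendall tau-b consistency of NES between evidence classes per ATC
level.  All randomness flows from the single config seed via fixed
per-stage stream tags.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cauchy, enrichment, expression, rank_engine
from .geneset_io import (
    DrugRecord,
    GeneSetCollection,
    build_atc_genesets,
    build_moa_genesets,
)

logger = logging.getLogger(__name__)

# enrichment-null stream tags per (evidence class, median variant)
_ARM_STREAMS = {
    ("common", "raw"): 11,
    ("common", "scaled"): 12,
    ("rare", "raw"): 13,
    ("rare", "scaled"): 14,
}


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; defaults are the standard analysis settings."""

    common_pvals: str | None = None
    transcript_pvals: str | None = None
    drug_table: str | None = None
    de_table: str | None = None
    seed: int = 0
    n_perm: int = 10_000
    weight_exponent: float = 1.0
    min_size: int = 5
    max_size: int = 500
    tie_rule: str = "average"
    tier_threshold: float = 0.05

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if self.tie_rule not in rank_engine.TIE_RULES:
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_drug_table(path) -> list[DrugRecord]:
    """Read a drug table: TSV with drug_id and comma-separated list columns."""
    df = pd.read_csv(path, sep="\t").fillna("")

    def split(cell) -> list[str]:
        return [x.strip() for x in str(cell).split(",") if x.strip()]

    return [
        DrugRecord(
            drug_id=str(row["drug_id"]),
            atc_codes=split(row.get("atc_codes", "")),
            target_genes=split(row.get("target_genes", "")),
            moa_labels=split(row.get("moa_labels", "")),
        )
        for _, row in df.iterrows()
    ]


def write_drug_table(drugs: list[DrugRecord], path) -> None:
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "atc_codes": [",".join(d.atc_codes) for d in drugs],
            "target_genes": [",".join(d.target_genes) for d in drugs],
            "moa_labels": [",".join(d.moa_labels) for d in drugs],
        }
    ).to_csv(path, sep="\t", index=False)


def build_collections(drugs: list[DrugRecord]) -> dict[str, GeneSetCollection]:
    """ATC level 2/3/4 and mechanism-of-action gene-set collections."""
    return {
        "atc2": build_atc_genesets(drugs, level=2),
        "atc3": build_atc_genesets(drugs, level=3),
        "atc4": build_atc_genesets(drugs, level=4),
        "moa": build_moa_genesets(drugs),
    }


def ranked_list_from_summary(summary: pd.DataFrame, which: str = "scaled") -> pd.DataFrame:
    """Turn a rank summary into a (gene_id, score) ranked list.

    The score is the chosen median rank value itself; with the engine's
    descending sort this puts the best genes at the bottom of the list,
    so enrichment among them shows up as negative ES.
    """
    column = {"raw": "raw_median", "scaled": "scaled_median"}[which]
    return summary[["gene_id", column]].rename(columns={column: "score"})


@dataclass
class GeneticArmResults:
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichments: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    nes_correlations: pd.DataFrame | None = None


def run_genetic_arm(
    config: PipelineConfig,
    common_pvals: pd.DataFrame | None = None,
    transcripts: pd.DataFrame | None = None,
    drugs: list[DrugRecord] | None = None,
) -> GeneticArmResults:
    """Rank fusion + enrichment for common and rare evidence, raw and scaled medians.

    Inputs may be passed in memory; otherwise they are read from the
    paths in the config (missing paths are rejected together, naming
    every absent file).
    """
    needed = []
    if common_pvals is None:
        needed.append(("common_pvals", config.common_pvals))
    if transcripts is None:
        needed.append(("transcript_pvals", config.transcript_pvals))
    if drugs is None:
        needed.append(("drug_table", config.drug_table))
    absent = [
        f"{name}={path!r}"
        for name, path in needed
        if path is None or not os.path.exists(path)
    ]
    if absent:
        raise ValueError(f"missing input files: {', '.join(absent)}")
    if common_pvals is None:
        common_pvals = rank_engine.read_pval_table(config.common_pvals)
    if transcripts is None:
        transcripts = cauchy.read_transcript_table(config.transcript_pvals)
    if drugs is None:
        drugs = read_drug_table(config.drug_table)

    results = GeneticArmResults()
    rare_pvals = cauchy.aggregate_gene_pvals(transcripts)
    for evidence_class, pvals in (("common", common_pvals), ("rare", rare_pvals)):
        ranks = rank_engine.rank_genes(pvals, tie_rule=config.tie_rule)
        summary = rank_engine.fuse_ranks(ranks)
        results.summaries[evidence_class] = summary
        logger.info("%s arm: %d genes ranked", evidence_class, len(summary))

    collections = build_collections(drugs)
    for evidence_class in ("common", "rare"):
        for variant in ("raw", "scaled"):
            ranked = ranked_list_from_summary(results.summaries[evidence_class], variant)
            rng = np.random.default_rng([config.seed, _ARM_STREAMS[(evidence_class, variant)]])
            tables = []
            for name, collection in collections.items():
                table = enrichment.run_enrichment(
                    ranked,
                    collection,
                    n_perm=config.n_perm,
                    weight_exponent=config.weight_exponent,
                    min_size=config.min_size,
                    max_size=config.max_size,
                    seed=rng,
                    tier_threshold=config.tier_threshold,
                )
                table.insert(0, "collection", name)
                tables.append(table)
            results.enrichments[(evidence_class, variant)] = pd.concat(
                tables, ignore_index=True
            )
            logger.info(
                "enrichment %s/%s: %d sets tested",
                evidence_class,
                variant,
                len(results.enrichments[(evidence_class, variant)]),
            )

    # cross-evidence consistency of NES per ATC level (scaled medians)
    corr_rows = []
    for name in ("atc2", "atc3", "atc4"):
        common_tab = results.enrichments[("common", "scaled")]
        rare_tab = results.enrichments[("rare", "scaled")]
        a = common_tab[common_tab["collection"] == name]
        b = rare_tab[rare_tab["collection"] == name]
        try:
            tau, p = enrichment.compare_nes_vectors(a, b)
        except ValueError:
            tau, p = float("nan"), float("nan")
        corr_rows.append({"collection": name, "kendall_tau": tau, "p_value": p})
    results.nes_correlations = pd.DataFrame(corr_rows)
    return results


def write_report(results: GeneticArmResults, out_dir, config: PipelineConfig | None = None) -> str:
    """Write all result tables plus a human-readable summary; returns the summary path.

    The resolved configuration (seed included) is written beside the
    outputs so any run can be reproduced bit-identically from it.
    """
    os.makedirs(out_dir, exist_ok=True)
    for evidence_class, summary in results.summaries.items():
        summary.to_csv(
            os.path.join(out_dir, f"rank_summary_{evidence_class}.tsv"),
            sep="\t",
            index=False,
        )
    for (evidence_class, variant), table in results.enrichments.items():
        table.to_csv(
            os.path.join(out_dir, f"enrichment_{evidence_class}_{variant}.tsv"),
            sep="\t",
            index=False,
        )
    if results.nes_correlations is not None:
        results.nes_correlations.to_csv(
            os.path.join(out_dir, "nes_correlations.tsv"), sep="\t", index=False
        )
    if config is not None:
        config.to_yaml(os.path.join(out_dir, "resolved_config.yaml"))

    summary_path = os.path.join(out_dir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write("Genetics-led repurposing: enrichment summary\n")
        fh.write("=" * 45 + "\n")
        for (evidence_class, variant), table in results.enrichments.items():
            flagged = table[table["tier"].isin(["strong", "moderate"])]
            fh.write(
                f"\n{evidence_class} variants, {variant} median: "
                f"{len(table)} sets tested, {len(flagged)} flagged\n"
            )
            for _, row in flagged.iterrows():
                fh.write(
                    f"  [{row['tier']:>8}] {row['collection']}:{row['set_id']} "
                    f"NES={row['nes']:.2f} q={row['fdr_q']:.3g} "
                    f"FWER={row['fwer_p']:.3g}\n"
                )
        if results.nes_correlations is not None:
            fh.write("\nCommon vs rare NES consistency (Kendall tau-b, scaled):\n")
            for _, row in results.nes_correlations.iterrows():
                fh.write(
                    f"  {row['collection']}: tau={row['kendall_tau']:.3f} "
                    f"p={row['p_value']:.3g}\n"
                )
    return summary_path
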