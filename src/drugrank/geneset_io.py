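"""Gene-set construction and GMT/RNK file plumbing.

Builds gene sets from drug-to-target tables keyed by Anatomical
Therapeutic Chemical (ATC) codes at levels 2/3/4 and by mechanism-of-
action (MoA) labels, and reads/writes the de facto standard GSEA file
formats: GMT (one gene set per line) and RNK (two-column ranked list,
no header).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# full ATC code: letter, 2 digits, letter, letter, 2 digits (e.g. L01EC02);
# valid prefixes have length 1, 3, 4 or 5
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_ATC_PREFIX = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
}

#: prefix length of each ATC level
ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with deduplicated, sorted members."""

    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        members = tuple(sorted(set(self.members)))
        if not members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered mapping of set_id -> GeneSet."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self._sets:
            raise ValueError(f"duplicate set_id {gene_set.set_id!r} in collection")
        self._sets[gene_set.set_id] = gene_set

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def set_ids(self) -> list[str]:
        return list(self._sets)


@dataclass
class DrugRecord:
    """One medicinal substance: its ATC codes, target genes and MoA labels."""

    drug_id: str
    atc_codes: list[str] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    moa_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        for code in self.atc_codes:
            validate_atc(code)
        self.target_genes = [g.strip().upper() for g in self.target_genes if g.strip()]


def validate_atc(code: str) -> str:
    """Validate an ATC code or prefix against the 7-character grammar."""
    code = code.strip().upper()
    ok = _ATC_FULL.match(code) or (
        len(code) in _ATC_PREFIX and _ATC_PREFIX[len(code)].match(code)
    )
    if not ok:
        raise ValueError(f"malformed ATC code {code!r}")
    return code


def truncate_atc(code: str, level: int) -> str:
    """Truncate an ATC code to a classification level (2 -> 3 chars, 3 -> 4, 4 -> 5).

    e.g. ``truncate_atc("L01EC02", 4) == "L01EC"`` (BRAF inhibitors),
    level 3 gives ``"L01E"`` (protein kinase inhibitors), level 2 gives
    ``"L01"`` (antineoplastic agents).
    """
    code = validate_atc(code)
    if level not in (2, 3, 4):
        raise ValueError(f"ATC truncation level must be 2, 3 or 4, got {level!r}")
    length = ATC_LEVEL_LENGTH[level]
    if len(code) < length:
        raise ValueError(f"ATC code {code!r} is shorter than level {level} ({length} chars)")
    return code[:length]


def _union_genesets(memberships: dict[str, set[str]], description: str) -> GeneSetCollection:
    collection = GeneSetCollection()
    for set_id in sorted(memberships):
        genes = memberships[set_id]
        if genes:
            collection.add(GeneSet(set_id, description, tuple(genes)))
    return collection


def build_atc_genesets(drugs: Iterable[DrugRecord], level: int) -> GeneSetCollection:
    """One gene set per truncated ATC code: the union of targets of all drugs carrying it.

    Drugs without ATC codes are skipped (counted in a log message); a
    drug with several codes contributes its targets to every one.
    """
    memberships: dict[str, set[str]] = {}
    skipped = 0
    for drug in drugs:
        if not drug.atc_codes:
            skipped += 1
            continue
        codes = {truncate_atc(c, level) for c in drug.atc_codes}
        for code in codes:
            memberships.setdefault(code, set()).update(drug.target_genes)
    if skipped:
        logger.info("build_atc_genesets: skipped %d drugs without ATC codes", skipped)
    return _union_genesets(memberships, f"ATC level {level}")


def build_moa_genesets(drugs: Iterable[DrugRecord]) -> GeneSetCollection:
    """One gene set per mechanism-of-action label (union of drug targets)."""
    memberships: dict[str, set[str]] = {}
    for drug in drugs:
        for label in drug.moa_labels:
            memberships.setdefault(label, set()).update(drug.target_genes)
    if not memberships:
        logger.warning("build_moa_genesets: no mechanism-of-action labels found")
    return _union_genesets(memberships, "mechanism of action")


def write_rnk(summary: pd.DataFrame, path, which: str = "scaled") -> None:
    """Write a rank summary as a two-column, headerless RNK file.

    ``which`` selects the raw or scaled median rank as the score column.
    """
    column = {"raw": "raw_median", "scaled": "scaled_median"}.get(which)
    if column is None:
        raise ValueError(f"which must be 'raw' or 'scaled', got {which!r}")
    if len(summary) == 0:
        raise ValueError("cannot write an empty rank summary")
    summary[["gene_id", column]].to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path) -> pd.DataFrame:
    """Read a headerless RNK file into a ranked-list frame (gene_id, score)."""
    ranked = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    ranked["gene_id"] = ranked["gene_id"].astype(str).str.strip().str.upper()
    dup = ranked["gene_id"].duplicated()
    if dup.any():
        sym = ranked.loc[dup, "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene symbol in RNK file: {sym!r}")
    ranked["score"] = ranked["score"].astype(float)
    return ranked


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT: set_id, description, then one gene per field."""
    with open(path, "w") as fh:
        for gene_set in collection:
            fields = [gene_set.set_id, gene_set.description, *gene_set.members]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; members are upper-cased and deduplicated."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields; expected at least 3"
                )
            members = tuple(g.strip().upper() for g in fields[2:] if g.strip())
            collection.add(GeneSet(fields[0], fields[1], members))
    return collection


def annotate_druggable_top_ranks(
    summary: pd.DataFrame,
    druggable: set[str],
    top_fraction: float = 0.05,
    column: str = "scaled_median",
) -> list[str]:
    """Druggable genes among the best top_fraction of ranks (ascending median).

    Mirrors the candidate-target annotation step: intersect the top x%
    of genes (rank values closest to 1) with a druggable-genome
    annotation.  Returns the hits in rank order.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction!r}")
    druggable_norm = {g.strip().upper() for g in druggable}
    if not druggable_norm:
        logger.warning("annotate_druggable_top_ranks: empty druggable set")
        return []
    n_top = int(np.ceil(top_fraction * len(summary)))
    best = summary.sort_values([column, "gene_id"], kind="stable").head(n_top)
    return [g for g in best["gene_id"] if g in druggable_norm]
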