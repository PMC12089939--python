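"""Clinical-tractability screen for repurposing candidates.

Evaluates Lipinski's rule of five — partition coefficient logP <= 5,
molecular weight < 500 Da, <= 10 hydrogen-bond acceptors, <= 5 donors —
for each compound, computing molecular weight from the molecular
formula when not annotated, and passing blood-brain-barrier (BBB)
permeability probabilities through for reporting.

logP and H-bond counts are predictor- and convention-dependent, so they
are taken as annotations; when no acceptor count is annotated the
classical N+O proxy is used and flagged approximate (counting
conventions demonstrably differ: e.g. vemurafenib has N+O = 6 but an
annotated acceptor count of 4).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

# Conventional IUPAC standard atomic weights (abridged to 4+ decimals).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.0983,
    "Ca": 40.078, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "As": 74.921595, "Se": 78.971, "Br": 79.904, "Mo": 95.95,
    "Ag": 107.8682, "I": 126.90447, "Pt": 195.084, "Au": 196.966569,
    "Hg": 200.592, "Bi": 208.9804,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element -> count.

    Accepts one- or two-letter element symbols with optional multi-digit
    counts (e.g. ``C63H91CoN13O14P``).  Unknown element symbols and
    malformed strings are rejected.
    """
    formula = formula.strip()
    if not formula:
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element, digits = match.groups()
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def molecular_weight(formula: str) -> float:
    """Molecular weight in Daltons: sum of count x standard atomic mass."""
    counts = parse_formula(formula)
    return sum(n * ATOMIC_MASSES[el] for el, n in counts.items())


def count_n_plus_o(formula: str) -> int:
    """Nitrogen + oxygen count: the classical Lipinski H-bond acceptor proxy.

    Only used when an explicit annotated acceptor count is absent; the
    result is approximate because annotation databases count acceptors
    chemically, not atomically.
    """
    counts = parse_formula(formula)
    return counts.get("N", 0) + counts.get("O", 0)


@dataclass
class CompoundProfile:
    """Per-compound tractability inputs (annotations plus formula)."""

    name: str
    molecular_formula: str | None = None
    log_p: float | None = None
    mw_da: float | None = None
    hbond_acceptors: int | None = None
    hbond_donors: int | None = None
    bbb_probability: float | None = None

    def __post_init__(self):
        if self.mw_da is None and self.molecular_formula:
            self.mw_da = molecular_weight(self.molecular_formula)
        if self.mw_da is not None and self.mw_da <= 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")
        if self.bbb_probability is not None and not 0 <= self.bbb_probability <= 1:
            raise ValueError(f"{self.name}: BBB probability must lie in [0, 1]")

    def resolved_acceptors(self) -> tuple[int | None, bool]:
        """Acceptor count and whether it came from the N+O proxy."""
        if self.hbond_acceptors is not None:
            return self.hbond_acceptors, False
        if self.molecular_formula:
            return count_n_plus_o(self.molecular_formula), True
        return None, False


@dataclass
class RuleOfFiveResult:
    """Per-criterion rule-of-five verdicts (None = property unavailable)."""

    name: str
    logp_ok: bool | None
    mw_ok: bool | None
    hba_ok: bool | None
    hbd_ok: bool | None
    hba_approximate: bool = False
    missing: list[str] = field(default_factory=list)

    @property
    def n_passed(self) -> int:
        return sum(bool(v) for v in (self.logp_ok, self.mw_ok, self.hba_ok, self.hbd_ok))

    @property
    def n_evaluated(self) -> int:
        return sum(v is not None for v in (self.logp_ok, self.mw_ok, self.hba_ok, self.hbd_ok))


def evaluate_rule_of_five(profile: CompoundProfile) -> RuleOfFiveResult:
    """Lipinski verdicts exactly as conventionally printed.

    logP <= 5; molecular weight strictly < 500 Da; H-bond acceptors
    <= 10; H-bond donors <= 5.  A missing property yields an absent
    verdict (excluded from ``n_passed``) and is listed in ``missing``.
    """
    missing = []
    logp_ok = None if profile.log_p is None else profile.log_p <= 5
    if logp_ok is None:
        missing.append("log_p")
    mw_ok = None if profile.mw_da is None else profile.mw_da < 500
    if mw_ok is None:
        missing.append("mw_da")
    hba, approximate = profile.resolved_acceptors()
    hba_ok = None if hba is None else hba <= 10
    if hba_ok is None:
        missing.append("hbond_acceptors")
    hbd_ok = None if profile.hbond_donors is None else profile.hbond_donors <= 5
    if hbd_ok is None:
        missing.append("hbond_donors")
    return RuleOfFiveResult(
        name=profile.name,
        logp_ok=logp_ok,
        mw_ok=mw_ok,
        hba_ok=hba_ok,
        hbd_ok=hbd_ok,
        hba_approximate=approximate,
        missing=missing,
    )


def _verdict(ok: bool | None, value) -> str:
    if ok is None:
        return ""
    shown = "" if value is None else f" ({value:g})" if isinstance(value, float) else f" ({value})"
    return ("Yes" if ok else "No") + shown


def tractability_report(profiles: Iterable[CompoundProfile]) -> pd.DataFrame:
    """One row per compound: rule-of-five verdict grid plus BBB pass-through.

    BBB probability is reported blank (not zero) when unannotated.
    """
    rows = []
    for profile in profiles:
        result = evaluate_rule_of_five(profile)
        hba, _ = profile.resolved_acceptors()
        mw = None if profile.mw_da is None else round(profile.mw_da, 2)
        rows.append(
            {
                "name": profile.name,
                "logp_le_5": _verdict(result.logp_ok, profile.log_p),
                "mw_lt_500": _verdict(result.mw_ok, mw),
                "hba_le_10": _verdict(result.hba_ok, hba),
                "hbd_le_5": _verdict(result.hbd_ok, profile.hbond_donors),
                "n_passed": result.n_passed,
                "bbb_probability": (
                    "" if profile.bbb_probability is None else f"{profile.bbb_probability:g}"
                ),
            }
        )
    columns = [
        "name", "logp_le_5", "mw_lt_500", "hba_le_10", "hbd_le_5",
        "n_passed", "bbb_probability",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_compound_table(path) -> list[CompoundProfile]:
    """Read a tab-separated compound table into profiles.

    Columns: ``name``, ``formula``, ``log_p`` and optionally ``mw``,
    ``hba``, ``hbd``, ``bbb_probability`` (blank = absent).
    """
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for _, row in df.iterrows():
        def _get(col, cast):
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return None
            return cast(val)

        profiles.append(
            CompoundProfile(
                name=str(row["name"]),
                molecular_formula=_get("formula", str),
                log_p=_get("log_p", float),
                mw_da=_get("mw", float),
                hbond_acceptors=_get("hba", int),
                hbond_donors=_get("hbd", int),
                bbb_probability=_get("bbb_probability", float),
            )
        )
    return profiles
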