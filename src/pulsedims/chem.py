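"""Elemental formulas, monoisotopic masses, adduct m/z, and accurate-mass annotation.

Direct-infusion metabolomics identifies features by matching observed m/z against
theoretical adduct masses of candidate metabolites within a ppm tolerance.  This
module provides the mass arithmetic for that: a small monoisotopic mass table
(most-abundant isotope, CODATA/IUPAC values), a Hill-notation formula parser,
the common singly-charged electrospray adducts, and a tolerance-based annotator.

All positive adducts subtract one electron mass per charge, so e.g. the proton
mass used for [M+H]+ is 1.00727646 Da, not the hydrogen atomic mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "AnnotationHit",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate",
    "read_candidates",
    "write_annotations",
    "round_half_up",
]

# Monoisotopic (most abundant isotope) atomic masses in Da, >= 6 decimals.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
#: Mass of a proton (H atom minus one electron); the delta applied by [M+H]+.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. C6H6N2O for niacinamide.

    ``counts`` maps element symbols to positive integer counts.  Only elements
    present in :data:`MONOISOTOPIC_MASS` are allowed.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"invalid count for {el}: {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da (sum of count x atomic mass)."""
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in self.counts.items())

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then other elements alphabetically."""
        parts = []
        order: list[str] = []
        if "C" in self.counts:
            order = ["C"] + (["H"] if "H" in self.counts else [])
            order += sorted(el for el in self.counts if el not in ("C", "H"))
        else:
            order = sorted(self.counts)
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular formula string such as ``"C43H78NO8P"``.

    A missing count means 1.  Raises :class:`FormulaError` on unknown symbols
    or malformed input.  Round-trips through :meth:`ElementalFormula.hill`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n == 0:
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula; the empty formula has mass 0."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.mass


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, signed mass delta (Da), and signed charge.

    ``mass_delta`` includes the electron mass correction (one electron removed
    per positive charge, added per negative charge).
    """

    name: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


def _delta(add: Mapping[str, int], charge: int) -> float:
    """Mass delta for attaching the given atoms at the given charge."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in add.items()) - charge * ELECTRON_MASS


_H2O = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

#: Supported singly-charged electrospray adducts.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", _delta({"H": 1}, +1), +1),
    "[M+Na]+": AdductSpec("[M+Na]+", _delta({"Na": 1}, +1), +1),
    "[M+K]+": AdductSpec("[M+K]+", _delta({"K": 1}, +1), +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _delta({"N": 1, "H": 4}, +1), +1),
    "[M+H-H2O]+": AdductSpec("[M+H-H2O]+", _delta({"H": 1}, +1) - _H2O, +1),
    "[M+NH4-H2O]+": AdductSpec("[M+NH4-H2O]+", _delta({"N": 1, "H": 4}, +1) - _H2O, +1),
    "[M-H]-": AdductSpec("[M-H]-", -MONOISOTOPIC_MASS["H"] + ELECTRON_MASS, -1),
}


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by name; unicode minus signs are normalized to '-'."""
    key = name.replace("−", "-").replace(" ", "")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(
            f"unsupported adduct {name!r}; supported: {', '.join(ADDUCTS)}"
        ) from None


def adduct_mz(formula: ElementalFormula | str, adduct: AdductSpec | str) -> float:
    """Theoretical m/z (Th) of ``formula`` ionized as ``adduct``.

    ``(monoisotopic mass + mass_delta) / |charge|``; only |z| = 1 adducts are
    shipped, so for them this is simply mass + delta.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    m = monoisotopic_mass(formula)
    return (m + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, as printed mass tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnnotationHit:
    """One candidate identity for an observed feature m/z."""

    feature_mz: float
    candidate_name: str
    formula: ElementalFormula
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float


def annotate(
    feature_mz: float,
    candidates: Sequence[tuple[str, ElementalFormula | str]],
    adducts: Iterable[AdductSpec | str] | None = None,
    tol_ppm: float = 10.0,
) -> list[AnnotationHit]:
    """All (candidate x adduct) matches within ``tol_ppm`` of ``feature_mz``.

    Results are sorted by |ppm error| ascending, ties broken by candidate name
    then adduct name, so the output is invariant to candidate-list order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adducts is None:
        adducts = list(ADDUCTS.values())
    specs = [get_adduct(a) if isinstance(a, str) else a for a in adducts]
    hits: list[AnnotationHit] = []
    for name, formula in candidates:
        if isinstance(formula, str):
            formula = parse_formula(formula)
        for spec in specs:
            theo = adduct_mz(formula, spec)
            err = ppm_error(feature_mz, theo)
            if abs(err) <= tol_ppm:
                hits.append(
                    AnnotationHit(feature_mz, name, formula, spec, theo, err)
                )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.candidate_name, h.adduct.name))
    return hits


def annotate_table(
    feature_mzs: Sequence[float],
    candidates: Sequence[tuple[str, ElementalFormula | str]],
    adducts: Iterable[AdductSpec | str] | None = None,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Annotate many feature m/z values; one row per hit."""
    rows = []
    for mz in feature_mzs:
        for h in annotate(mz, candidates, adducts, tol_ppm):
            rows.append(
                {
                    "feature_mz": h.feature_mz,
                    "name": h.candidate_name,
                    "formula": h.formula.hill(),
                    "adduct": h.adduct.name,
                    "theoretical_mz": round_half_up(h.theoretical_mz, 4),
                    "ppm_error": h.ppm_error,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature_mz", "name", "formula", "adduct", "theoretical_mz", "ppm_error"],
    )


def read_candidates(path) -> list[tuple[str, ElementalFormula]]:
    """Read a candidate list CSV with columns ``name`` and ``formula``."""
    df = pd.read_csv(path)
    missing = {"name", "formula"} - set(df.columns)
    if missing:
        raise ValueError(f"candidate CSV missing columns: {sorted(missing)}")
    return [(str(r["name"]), parse_formula(str(r["formula"]))) for _, r in df.iterrows()]


def write_annotations(df: pd.DataFrame, path) -> None:
    """Write an annotation result table as CSV."""
    df.to_csv(path, index=False)
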