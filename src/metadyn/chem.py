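"""Sum-formula arithmetic and accurate-mass ion annotation.

Untargeted flow-injection TOF mass spectra (negative-mode electrospray) are
annotated purely by accurate mass: for every metabolite in a reference
library the neutral monoisotopic mass is computed from its sum formula, the
deprotonated [M-H]- m/z is derived, and measured ion m/z values are matched
against those expected masses within a small tolerance (0.003 Da by
default).  Because flow injection provides no chromatographic separation,
isobaric metabolites collapse onto a single ion; all matches within the
tolerance window are retained and the single reported annotation is the one
with the smallest absolute mass error.

Alpha-keto acids react with the phenylhydrazine spiked into the extraction
solvent; their phenylhydrazone derivatives (net formula change +C6H8N2,
-H2O) are added to the ion library for metabolites flagged ``is_keto_acid``.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "SumFormula",
    "MetaboliteRecord",
    "IonLibraryEntry",
    "Annotation",
    "FormulaParseError",
    "DerivatizationError",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "phenylhydrazone_formula",
    "build_ion_library",
    "annotate_ions",
]

#: Monoisotopic masses (Da) of the most abundant isotope of each element
#: (NIST/CODATA atomic mass evaluation, >= 8 decimals).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Se": 79.9165213,
    "Fe": 55.9349375,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Zn": 63.9291422,
}

#: Mass of the proton (Da): hydrogen-atom mass minus the electron mass.
#: Deprotonation in negative mode removes H+ and leaves the electron behind,
#: so [M-H]- m/z = M - PROTON_MASS.
PROTON_MASS = 1.007276467


class FormulaParseError(ValueError):
    """Raised when a sum-formula string cannot be parsed."""


class DerivatizationError(ValueError):
    """Raised when a formula cannot undergo phenylhydrazone derivatization."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class SumFormula:
    """Elemental composition as a mapping element symbol -> count.

    The empty formula (mass 0) is valid.  Instances are immutable and
    hashable; counts of zero are dropped on construction.
    """

    counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        cleaned = []
        for sym, n in dict(self.counts).items():
            if sym not in ELEMENT_MASSES:
                raise FormulaParseError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise FormulaParseError(f"negative count for element {sym!r}")
            if n > 0:
                cleaned.append((sym, int(n)))
        object.__setattr__(self, "counts", tuple(sorted(cleaned)))

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "SumFormula":
        return cls(tuple(counts.items()))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "SumFormula") -> "SumFormula":
        merged = dict(self.counts)
        for sym, n in other.counts:
            merged[sym] = merged.get(sym, 0) + n
        return SumFormula.from_dict(merged)

    def __str__(self) -> str:
        return canonical_string(self)


def canonical_string(formula: SumFormula) -> str:
    """Hill-order string: C first, then H, then other elements alphabetically.

    Without carbon, all elements are listed alphabetically.  Count 1 is
    implicit.  The empty formula renders as the empty string.
    """
    counts = formula.as_dict()
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(e for e in counts if e not in ("C", "H"))
    else:
        order = sorted(counts)
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def parse_formula(text: str) -> SumFormula:
    """Parse a flat sum-formula string such as ``"C9H17NO5"``.

    Repeated element mentions accumulate.  Parentheses, charges, isotope
    labels and hydrate dots are not part of the grammar; reference tables
    must provide pre-expanded flat formulas.

    Raises
    ------
    FormulaParseError
        If the text contains an unknown element symbol (the symbol is named)
        or is malformed (the character position is reported).
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaParseError(
                f"malformed formula {text!r} at position {pos}"
            )
        sym, digits = match.group(1), match.group(2)
        if sym not in ELEMENT_MASSES:
            raise FormulaParseError(f"unknown element symbol: {sym!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaParseError(f"malformed formula {text!r} at position {pos}")
    return SumFormula.from_dict(counts)


def monoisotopic_mass(formula: SumFormula) -> float:
    """Neutral monoisotopic mass (Da): sum of most-abundant-isotope masses."""
    return sum(ELEMENT_MASSES[sym] * n for sym, n in formula.counts)


def deprotonated_mz(neutral_mass: float) -> float:
    """m/z of the [M-H]- ion: neutral mass minus the proton mass."""
    mz = neutral_mass - PROTON_MASS
    if mz <= 0:
        raise ValueError(
            f"deprotonated m/z non-positive for neutral mass {neutral_mass}"
        )
    return mz


_PHENYLHYDRAZONE_GAIN = SumFormula.from_dict({"C": 6, "H": 8, "N": 2})


def phenylhydrazone_formula(formula: SumFormula) -> SumFormula:
    """Apply the phenylhydrazone derivatization rule +C6H8N2 -H2O.

    The condensation requires a carbonyl plus two hydrogens to leave as
    water, i.e. at least H2 and O1 in the substrate formula.
    """
    counts = formula.as_dict()
    if counts.get("H", 0) < 2 or counts.get("O", 0) < 1:
        raise DerivatizationError(
            f"formula {canonical_string(formula)!r} lacks the H2/O1 required "
            "for phenylhydrazone formation"
        )
    counts["C"] = counts.get("C", 0) + 6
    counts["H"] = counts["H"] + 8 - 2
    counts["N"] = counts.get("N", 0) + 2
    counts["O"] = counts["O"] - 1
    return SumFormula.from_dict(counts)


@dataclass(frozen=True)
class MetaboliteRecord:
    """Reference metabolite (HMDB/Recon-style export row)."""

    id: str
    name: str
    formula: SumFormula
    is_keto_acid: bool = False
    source: str = ""
    neutral_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mass = monoisotopic_mass(self.formula)
        if self.neutral_mass is None:
            object.__setattr__(self, "neutral_mass", mass)
        elif abs(self.neutral_mass - mass) > 1e-9:
            raise ValueError(
                f"neutral_mass {self.neutral_mass} inconsistent with formula "
                f"{canonical_string(self.formula)} (computed {mass})"
            )


@dataclass(frozen=True)
class IonLibraryEntry:
    """One expected [M-H]- m/z, optionally of a phenylhydrazone derivative."""

    metabolite_id: str
    expected_mz: float
    derivatized: bool = False


@dataclass(frozen=True)
class Annotation:
    """Best-match annotation of one measured ion.

    ``mass_error`` is signed, measured minus expected.  ``all_matches``
    lists every library entry within tolerance as
    (metabolite_id, mass_error, derivatized) tuples.
    """

    ion_mz: float
    best_metabolite_id: str
    mass_error: float
    derivatized: bool
    all_matches: tuple[tuple[str, float, bool], ...]


def build_ion_library(metabolites: list[MetaboliteRecord]) -> list[IonLibraryEntry]:
    """Expected-ion library: one [M-H]- entry per metabolite, plus one
    derivatized entry per alpha-keto acid.  Entries are sorted by m/z."""
    seen: set[str] = set()
    entries: list[IonLibraryEntry] = []
    for met in metabolites:
        if met.id in seen:
            raise ValueError(f"duplicate metabolite id: {met.id!r}")
        seen.add(met.id)
        entries.append(
            IonLibraryEntry(met.id, deprotonated_mz(met.neutral_mass), False)
        )
        if met.is_keto_acid:
            deriv = phenylhydrazone_formula(met.formula)
            entries.append(
                IonLibraryEntry(
                    met.id, deprotonated_mz(monoisotopic_mass(deriv)), True
                )
            )
    entries.sort(key=lambda e: (e.expected_mz, e.metabolite_id, e.derivatized))
    return entries


def annotate_ions(
    ion_mzs: list[float],
    library: list[IonLibraryEntry],
    tolerance: float = 0.003,
) -> list[Annotation]:
    """Match measured ion m/z values against an expected-ion library.

    All library entries within ``tolerance`` (inclusive) of an ion are
    collected; the best match minimizes |mass error|, ties broken by
    lexicographically smallest metabolite id for determinism.  Ions without
    any match yield no Annotation.  Runtime O((n + m) log m) via binary
    search on the m/z-sorted library.
    """
    if not library:
        raise ValueError("empty ion library")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lib = sorted(library, key=lambda e: e.expected_mz)
    mzs = [e.expected_mz for e in lib]
    out: list[Annotation] = []
    for ion in ion_mzs:
        lo = bisect_left(mzs, ion - tolerance)
        hi = bisect_right(mzs, ion + tolerance)
        matches = [
            (e.metabolite_id, ion - e.expected_mz, e.derivatized)
            for e in lib[lo:hi]
            if abs(ion - e.expected_mz) <= tolerance
        ]
        if not matches:
            continue
        best = min(matches, key=lambda m: (abs(m[1]), m[0]))
        out.append(
            Annotation(
                ion_mz=ion,
                best_metabolite_id=best[0],
                mass_error=best[1],
                derivatized=best[2],
                all_matches=tuple(sorted(matches, key=lambda m: (abs(m[1]), m[0]))),
            )
        )
    return out
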