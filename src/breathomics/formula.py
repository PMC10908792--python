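"""Molecular formulas and monoisotopic mass arithmetic.

Formulas are the unit of putative identification throughout the pipeline:
direct-infusion FT-ICR-MS resolves ions well enough that an exact mass,
together with the isotopic fine structure, pins down an elemental
composition but not a structure.  Atomic masses and isotope abundances come
from the NIST table bundled with :mod:`pyteomics`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

from pyteomics import mass as _pmass

#: CODATA mass of the electron in Da.
ELECTRON_MASS = 0.00054857990907
#: Mass of the proton (H nucleus) in Da.
PROTON_MASS = 1.00727646688

#: Elements accepted in formulas. Covers the organic metabolome plus the
#: halogens and metals that occur in the annotation lists and adducts.
ALLOWED_ELEMENTS = (
    "C", "H", "N", "O", "P", "S",
    "F", "Cl", "Br", "I",
    "Na", "K", "Ca", "Mg", "Se",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formula strings."""


def monoisotopic_atomic_mass(element: str) -> float:
    """Mass in Da of the element's principal (most abundant) isotope."""
    if element not in ALLOWED_ELEMENTS:
        raise FormulaError(f"unknown element symbol: {element!r}")
    return _pmass.nist_mass[element][0][0]


def isotope_table(element: str) -> List[Tuple[float, float]]:
    """Naturally occurring isotopes of *element* as (mass Da, abundance).

    Sorted by mass; abundances sum to 1 (zero-abundance entries of the NIST
    table are dropped).
    """
    if element not in ALLOWED_ELEMENTS:
        raise FormulaError(f"unknown element symbol: {element!r}")
    rows = [
        (m, ab)
        for key, (m, ab) in _pmass.nist_mass[element].items()
        if key != 0 and ab > 0.0
    ]
    rows.sort()
    return rows


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition, e.g. ``C5H9NO2`` for proline.

    ``element_counts`` maps element symbols to strictly positive counts.
    Instances are immutable and hashable so they can key feature tables.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        for el, n in counts.items():
            if el not in ALLOWED_ELEMENTS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise FormulaError(f"non-positive count for {el}: {n!r}")
        object.__setattr__(self, "element_counts", counts)

    def __hash__(self) -> int:  # mapping field is not hashable by default
        return hash(tuple(sorted(self.element_counts.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemicalFormula):
            return NotImplemented
        return dict(self.element_counts) == dict(other.element_counts)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(sorted(self.element_counts.items()))

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"ChemicalFormula({format_formula(self)!r})"


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation-like formula string.

    Accepts element symbols with optional integer counts (``C5H9NO2``,
    ``H2O``). Repeated symbols accumulate. Raises :class:`FormulaError` on
    empty input, unknown symbols or explicit zero counts.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        el, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count in {text!r} for {el}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return ChemicalFormula(counts)


def format_formula(formula: ChemicalFormula) -> str:
    """Canonical Hill-order string: C, then H, then other elements A-Z."""
    counts = dict(formula.element_counts)
    ordered: List[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(sorted(el for el in counts if el not in ("C", "H")))
    else:
        ordered.extend(sorted(counts))
    return "".join(
        f"{el}{counts[el]}" if counts[el] != 1 else el for el in ordered
    )


def monoisotopic_mass(formula: ChemicalFormula) -> float:
    """Monoisotopic (principal-isotope) mass of the neutral formula in Da."""
    return sum(
        n * monoisotopic_atomic_mass(el) for el, n in formula.element_counts.items()
    )
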