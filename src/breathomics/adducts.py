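"""Electrospray adducts and ion m/z arithmetic.

Direct-infusion ESI of small molecules yields almost exclusively singly
charged ions.  Besides (de)protonation, only sodium, potassium and chloride
attachment are considered, the species that survive direct injection
without chromatographic separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .formula import (
    ChemicalFormula,
    ELECTRON_MASS,
    monoisotopic_atomic_mass,
    monoisotopic_mass,
)

_H = monoisotopic_atomic_mass("H")
_NA = monoisotopic_atomic_mass("Na")
_K = monoisotopic_atomic_mass("K")
_CL = monoisotopic_atomic_mass("Cl")


@dataclass(frozen=True)
class AdductRule:
    """An ionisation rule [M+X]z.

    ``mass_delta`` is the *neutral* mass change in Da (the attached or
    removed atoms); the electron imbalance implied by ``charge`` is applied
    separately in :func:`theoretical_mz`, so at the sub-ppm tolerances used
    here ion masses remain exact below ~550 m/z.
    """

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(
                f"adduct {self.name}: charge sign inconsistent with polarity"
            )


#: [M+H]+, [M+Na]+, [M+K]+ — positive-mode ion species.
POSITIVE_ADDUCTS: List[AdductRule] = [
    AdductRule("[M+H]+", "positive", _H, +1),
    AdductRule("[M+Na]+", "positive", _NA, +1),
    AdductRule("[M+K]+", "positive", _K, +1),
]

#: [M-H]-, [M+Cl]- — negative-mode ion species.
NEGATIVE_ADDUCTS: List[AdductRule] = [
    AdductRule("[M-H]-", "negative", -_H, -1),
    AdductRule("[M+Cl]-", "negative", _CL, -1),
]

DEFAULT_ADDUCTS: List[AdductRule] = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS


def adducts_for_mode(mode: str) -> List[AdductRule]:
    """The default adduct set for an ionisation mode."""
    if mode == "positive":
        return list(POSITIVE_ADDUCTS)
    if mode == "negative":
        return list(NEGATIVE_ADDUCTS)
    raise ValueError(f"unknown ionisation mode {mode!r}")


def ion_mass_shift(adduct: AdductRule) -> float:
    """Observed m/z minus neutral monoisotopic mass for a |z|=1 adduct."""
    return adduct.mass_delta - adduct.charge * ELECTRON_MASS


def theoretical_mz(formula: ChemicalFormula, adduct: AdductRule) -> float:
    """m/z of the principal isotopologue of [formula + adduct]."""
    if adduct.charge == 0:
        raise ValueError("charge must be non-zero")
    m = monoisotopic_mass(formula) + adduct.mass_delta - adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
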