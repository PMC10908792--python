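"""Isotopic fine-structure simulation and pattern fit scoring.

At a resolving power of ~500k the FT-ICR instrument separates the
isotopologue sub-peaks of small molecules (e.g. the 13C vs 15N satellites
of an amino acid).  Agreement between the observed and the simulated fine
structure is the second gate, after mass error, for accepting a formula
annotation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _pmass

from .adducts import AdductRule, ion_mass_shift
from .formula import ChemicalFormula, format_formula


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotopologue peaks as (m/z, abundance relative to base).

    m/z values are strictly increasing; the base (most abundant) peak has
    relative abundance 1.
    """

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("isotope pattern must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("pattern m/z values must be strictly increasing")
        if any(a <= 0 for _, a in self.peaks):
            raise ValueError("pattern abundances must be positive")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def base_mz(self) -> float:
        """m/z of the most abundant peak."""
        return self.peaks[int(np.argmax(self.abundance))][0]


@functools.lru_cache(maxsize=4096)
def _isotopologues(formula_str: str, floor: float) -> Tuple[Tuple[float, float], ...]:
    """Exhaustive isotopologue (mass, probability) list above ``floor``."""
    out = []
    for comp, ab in _pmass.isotopologues(
        formula=formula_str, report_abundance=True, overall_threshold=floor
    ):
        out.append((_pmass.calculate_mass(comp), ab))
    out.sort()
    return tuple(out)


def isotope_pattern(
    formula: ChemicalFormula,
    resolving_power: float = 488_000.0,
    abundance_floor: float = 1e-3,
    mz_shift: float = 0.0,
    adduct: Optional[AdductRule] = None,
) -> IsotopePattern:
    """Simulate the isotopic fine structure of a neutral formula or its ion.

    Isotopologue probabilities come from a multinomial expansion over
    natural abundances; peaks closer than the FWHM implied by
    ``resolving_power`` (taken as m/FWHM at the peak's own m/z) are merged
    into an abundance-weighted centroid; abundances are reported relative
    to the base peak and truncated below ``abundance_floor``.

    ``adduct`` (or a raw ``mz_shift`` in Da) moves the mass scale to the
    ion; adduct atoms are treated as monoisotopic, a good approximation for
    H/Na/K and adequate for Cl at the default floor.
    """
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    if adduct is not None:
        mz_shift = ion_mass_shift(adduct)
    raw = _isotopologues(format_formula(formula), abundance_floor * 1e-3)
    masses = np.array([m for m, _ in raw]) + mz_shift
    probs = np.array([p for _, p in raw])

    # greedy left-to-right merge of peaks unresolved at this resolving power
    merged_mz: List[float] = []
    merged_ab: List[float] = []
    for m, p in zip(masses, probs):
        if merged_mz and (m - merged_mz[-1]) < m / resolving_power:
            tot = merged_ab[-1] + p
            merged_mz[-1] = (merged_mz[-1] * merged_ab[-1] + m * p) / tot
            merged_ab[-1] = tot
        else:
            merged_mz.append(m)
            merged_ab.append(p)

    ab = np.array(merged_ab)
    rel = ab / ab.max()
    keep = rel >= abundance_floor
    return IsotopePattern(
        tuple((mz, r) for mz, r in zip(np.array(merged_mz)[keep], rel[keep]))
    )


def isotope_fit_score(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    match_ppm: float = 2.0,
) -> float:
    """Fine-structure fit score: 0 = perfect, larger = worse.

    Theoretical peaks are matched to the closest observed peak within
    ``match_ppm``; the score is 1000 x the weighted RMS relative deviation
    of the matched abundances, with weights sqrt(theoretical abundance) so
    that strong isotopologues dominate but a missing satellite still incurs
    its full deviation of 1.  On this scale a uniform ~30% abundance error
    scores near 300, the customary acceptance cut-off for fine-structure
    agreement.
    """
    obs_mz = observed.mz
    obs_ab = observed.abundance
    devs = []
    weights = []
    base_matched = False
    base_idx = int(np.argmax(theoretical.abundance))
    for i, (mz_t, ab_t) in enumerate(theoretical.peaks):
        j = int(np.argmin(np.abs(obs_mz - mz_t)))
        w = float(np.sqrt(ab_t))
        if abs(obs_mz[j] - mz_t) / mz_t * 1e6 <= match_ppm:
            dev = (obs_ab[j] - ab_t) / ab_t
            if i == base_idx:
                base_matched = True
        else:
            dev = 1.0  # theoretical peak absent from the observation
        devs.append(dev)
        weights.append(w)
    if not base_matched:
        raise ValueError("observed pattern has no peak matching the base peak")
    d = np.asarray(devs)
    w = np.asarray(weights)
    return float(1000.0 * np.sqrt(np.sum(w * d**2) / np.sum(w)))
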