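"""Synthetic breath-cohort generator with known ground truth.

Emulates the study conditions end to end: ~100 subjects each contributing
three breath-filter extracts, every extract acquired in two ionisation
modes and two mass-range methods on a direct-infusion FT-ICR instrument,
with pooled-QC injections interleaved into each sequence.  The noise model
is multiplicative (log-normal): a per-extract dilution factor (variable
droplet yield), per-batch factors, per-acquisition intensity scatter,
detection dropout below the limit of detection, and sub-ppm m/z jitter.
Planted covariate effects (gender, contraceptive use, alcohol, ...) are
recorded in a truth manifest so that downstream recovery is measurable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adducts import AdductRule, NEGATIVE_ADDUCTS, POSITIVE_ADDUCTS, theoretical_mz
from .annotate import ReferenceRecord
from .formula import ChemicalFormula, format_formula
from .isotopes import isotope_pattern
from .peaks import METHOD_WINDOWS, PeakList
from .refdata import build_reference_list

MODES = ("positive", "negative")

#: Cohort category frequencies (fractions of the study population).
DEFAULT_PHENOTYPE_FREQS: Dict[str, object] = {
    "female": 50 / 101,
    "oc_use_given_female": 16 / 50,
    "alcohol": {"regular": 53 / 101, "occasional": 28 / 101, "none": 20 / 101},
    "smoking": 10 / 101,
    "coffee": 92 / 101,
    "diet": {"flexitarian": 68 / 101, "vegetarian": 28 / 101, "vegan": 5 / 101},
    "activity": {"regular": 56 / 101, "occasional": 34 / 101, "none": 11 / 101},
    "supplements": 45 / 101,
    "allergies": 15 / 101,
}


@dataclass(frozen=True)
class PhenotypeProfile:
    """Subject-level covariates driving grouping and planted effects."""

    subject_id: str
    gender: str  # "female" | "male"
    oc_use: bool
    alcohol: str  # "regular" | "occasional" | "none"
    smoking: bool
    coffee: bool
    diet: str  # "flexitarian" | "vegetarian" | "vegan"
    activity: str  # "regular" | "occasional" | "none"
    supplements: bool
    allergies: bool = False

    def __post_init__(self) -> None:
        if self.gender == "male" and self.oc_use:
            raise ValueError("oc_use must be False for male subjects")


#: How a covariate name maps to the affected subgroup.
def covariate_indicator(profile: PhenotypeProfile, covariate: str) -> bool:
    if covariate == "gender":
        return profile.gender == "female"
    if covariate == "oc_use":
        return profile.oc_use
    if covariate == "alcohol":
        return profile.alcohol == "none"
    if covariate == "smoking":
        return profile.smoking
    if covariate == "coffee":
        return profile.coffee
    if covariate == "diet":
        return profile.diet != "flexitarian"
    if covariate == "activity":
        return profile.activity == "regular"
    if covariate == "supplements":
        return profile.supplements
    if covariate == "allergies":
        return profile.allergies
    raise KeyError(f"unknown covariate {covariate!r}")


@dataclass(frozen=True)
class GroundTruthMetabolite:
    """One panel member with its intensity model and planted effects."""

    db_id: str
    formula: ChemicalFormula
    base_log_intensity: float  # log10 counts in the reference subject
    mode_efficiency: Mapping[str, float]  # polarity -> ionisation yield [0,1]
    adduct: Mapping[str, AdductRule]  # polarity -> ion species
    detection_prob: float
    effects: Mapping[str, float]  # covariate -> multiplicative fold

    def expected_intensity(self, profile: PhenotypeProfile, mode: str) -> float:
        x = 10.0**self.base_log_intensity * self.mode_efficiency[mode]
        for cov, fold in self.effects.items():
            if covariate_indicator(profile, cov):
                x *= fold
        return x


@dataclass
class EffectSpec:
    """Planted-effect request: which covariates mark how many metabolites."""

    covariate: str
    n_markers: int
    fold_range: Tuple[float, float] = (2.0, 4.0)
    both_directions: bool = True  # halve/double symmetric about 1


@dataclass
class CohortDesign:
    """Sizes, noise levels and acquisition layout of a simulated study."""

    n_subjects: int = 101
    replicates_per_subject: int = 3
    n_batches: int = 2
    qc_interval: int = 12
    mass_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(METHOD_WINDOWS)
    )
    ppm_noise_sd: float = 0.3  # so a 1 ppm gate keeps ~99.9% of true matches
    lod: float = 1e6  # counts
    dilution_sd: float = 0.2  # log10 per-extract dilution scatter
    replicate_sd: float = 0.15  # log10 per-acquisition intensity scatter
    batch_sd: float = 0.15  # log10 of per-batch factors
    qc_noise_sd: float = 0.05  # log10 scatter of pooled-QC injections
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_subject < 2:
            raise ValueError("need at least 2 replicates per subject")
        if self.n_subjects < 1 or self.n_batches < 1:
            raise ValueError("n_subjects and n_batches must be positive")


def generate_phenotypes(
    n_subjects: int,
    rng: np.random.Generator,
    freqs: Optional[Mapping[str, object]] = None,
) -> List[PhenotypeProfile]:
    """Draw subject profiles with the configured category frequencies."""
    f = dict(DEFAULT_PHENOTYPE_FREQS)
    if freqs:
        f.update(freqs)

    def pick(dist: Mapping[str, float]) -> str:
        keys = list(dist)
        p = np.array([dist[k] for k in keys], dtype=float)
        return str(rng.choice(keys, p=p / p.sum()))

    profiles = []
    for i in range(n_subjects):
        female = rng.random() < f["female"]
        profiles.append(
            PhenotypeProfile(
                subject_id=f"S{i + 1:03d}",
                gender="female" if female else "male",
                oc_use=bool(female and rng.random() < f["oc_use_given_female"]),
                alcohol=pick(f["alcohol"]),
                smoking=bool(rng.random() < f["smoking"]),
                coffee=bool(rng.random() < f["coffee"]),
                diet=pick(f["diet"]),
                activity=pick(f["activity"]),
                supplements=bool(rng.random() < f["supplements"]),
                allergies=bool(rng.random() < f["allergies"]),
            )
        )
    return profiles


def phenotypes_to_frame(profiles: Sequence[PhenotypeProfile]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
    return df.set_index("subject_id")


def generate_panel(
    n_metabolites: int,
    effect_spec: Sequence[EffectSpec],
    seed: int,
    reference: Optional[Sequence[ReferenceRecord]] = None,
    base_log_range: Tuple[float, float] = (6.8, 8.5),
) -> Tuple[List[GroundTruthMetabolite], Dict[str, Dict[str, float]]]:
    """Draw a ground-truth metabolite panel from a reference list.

    Returns the panel and a marker manifest {covariate: {db_id: fold}}.
    Fold effects multiply the affected subgroup's intensities; with
    ``both_directions`` half the markers are inverted (fold -> 1/fold) so
    both orientations occur, as in real group contrasts.
    """
    rng = np.random.default_rng(seed)
    reference = list(reference) if reference is not None else build_reference_list()
    for spec in effect_spec:
        if spec.n_markers > n_metabolites:
            raise ValueError(
                f"{spec.covariate}: {spec.n_markers} markers requested "
                f"but panel has only {n_metabolites} metabolites"
            )
    if n_metabolites > len(reference):
        raise ValueError("panel larger than the reference list")
    chosen = rng.choice(len(reference), size=n_metabolites, replace=False)
    records = [reference[int(i)] for i in chosen]

    effects_per_met: List[Dict[str, float]] = [dict() for _ in records]
    manifest: Dict[str, Dict[str, float]] = {}
    for spec in effect_spec:
        ids = rng.choice(n_metabolites, size=spec.n_markers, replace=False)
        manifest[spec.covariate] = {}
        for k in ids:
            fold = float(rng.uniform(*spec.fold_range))
            if spec.both_directions and rng.random() < 0.5:
                fold = 1.0 / fold
            effects_per_met[int(k)][spec.covariate] = fold
            manifest[spec.covariate][records[int(k)].db_id] = fold

    panel: List[GroundTruthMetabolite] = []
    for rec, eff in zip(records, effects_per_met):
        preferred = MODES[int(rng.random() < 0.5)]
        mode_eff = {}
        for mode in MODES:
            if mode == preferred:
                mode_eff[mode] = float(rng.uniform(0.6, 1.0))
            else:
                mode_eff[mode] = float(rng.uniform(0.1, 0.9))
        adduct = {
            "positive": POSITIVE_ADDUCTS[0]
            if rng.random() < 0.8
            else POSITIVE_ADDUCTS[int(rng.integers(1, len(POSITIVE_ADDUCTS)))],
            "negative": NEGATIVE_ADDUCTS[0]
            if rng.random() < 0.8
            else NEGATIVE_ADDUCTS[1],
        }
        panel.append(
            GroundTruthMetabolite(
                db_id=rec.db_id,
                formula=rec.formula,
                base_log_intensity=float(rng.uniform(*base_log_range)),
                mode_efficiency=mode_eff,
                adduct=adduct,
                # sporadic acquisition-level failures are rare for peaks above
                # the detection limit; near-LOD dropout emerges from the noise
                detection_prob=float(rng.uniform(0.98, 1.0)),
                effects=eff,
            )
        )
    return panel, manifest


class _PanelIndex:
    """Precomputed ion m/z and principal isotopologues per (metabolite, mode)."""

    def __init__(self, panel: Sequence[GroundTruthMetabolite], iso_floor: float = 0.01,
                 max_iso_peaks: int = 3):
        self.panel = list(panel)
        self.ion: Dict[str, List[np.ndarray]] = {}
        for mode in MODES:
            per_met = []
            for met in self.panel:
                pat = isotope_pattern(
                    met.formula, abundance_floor=iso_floor, adduct=met.adduct[mode]
                )
                order = np.argsort(-pat.abundance)[:max_iso_peaks]
                keep = np.sort(order)
                per_met.append(np.column_stack([pat.mz[keep], pat.abundance[keep]]))
            self.ion[mode] = per_met


def _simulate_acquisition(
    index: _PanelIndex,
    profile: PhenotypeProfile,
    design: CohortDesign,
    rng: np.random.Generator,
    mode: str,
    method: str,
    scale: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """(mz, intensity) arrays for one injection of one extract."""
    lo, hi = design.mass_ranges[method]
    mzs: List[float] = []
    intens: List[float] = []
    for met, iso in zip(index.panel, index.ion[mode]):
        expected = met.expected_intensity(profile, mode) * scale
        noisy = expected * 10.0 ** rng.normal(0.0, design.replicate_sd)
        if rng.random() >= met.detection_prob:
            continue
        for mz_t, rel in iso:
            inten = noisy * rel
            if inten < design.lod:
                continue
            mz_obs = mz_t * (1.0 + rng.normal(0.0, design.ppm_noise_sd) * 1e-6)
            if lo <= mz_obs <= hi:
                mzs.append(float(mz_obs))
                intens.append(float(inten))
    return np.asarray(mzs), np.asarray(intens)


def simulate_sample(
    profile: PhenotypeProfile,
    panel: Sequence[GroundTruthMetabolite],
    design: CohortDesign,
    rng: np.random.Generator,
    replicate_index: int = 1,
    dilution: float = 1.0,
    batch: str = "B1",
    batch_factor: float = 1.0,
    _index: Optional[_PanelIndex] = None,
) -> List[PeakList]:
    """Simulate one extract: 2 modes x 2 mass-range methods = 4 peak lists."""
    index = _index if _index is not None else _PanelIndex(panel)
    out = []
    for mode in MODES:
        for method in design.mass_ranges:
            mz, inten = _simulate_acquisition(
                index, profile, design, rng, mode, method,
                scale=dilution * batch_factor,
            )
            out.append(
                PeakList(
                    sample_id=f"{profile.subject_id}_r{replicate_index}_{mode[:3]}_{method}",
                    subject_id=profile.subject_id,
                    replicate_index=replicate_index,
                    mode=mode,
                    method=method,
                    batch=batch,
                    mz=mz,
                    intensity=inten,
                )
            )
    return out


def qc_schedule(n_analytical: int, interval: int) -> List[int]:
    """Positions (0..n) in the analytical sequence before which a QC runs.

    A pooled QC is injected at the start, after every ``interval``
    analytical samples, and at the end of the sequence (deduplicated when
    the sequence length is a multiple of the interval).
    """
    pos = [0] + list(range(interval, n_analytical + 1, interval))
    if pos[-1] != n_analytical:
        pos.append(n_analytical)
    return pos


@dataclass
class StudyDataset:
    """Everything a simulated study produces."""

    peak_lists: List[PeakList]
    phenotypes: pd.DataFrame
    panel: List[GroundTruthMetabolite]
    manifest: Dict[str, object]

    @property
    def analytical(self) -> List[PeakList]:
        return [p for p in self.peak_lists if not p.is_qc]

    @property
    def qcs(self) -> List[PeakList]:
        return [p for p in self.peak_lists if p.is_qc]


def simulate_study(
    design: CohortDesign,
    panel: Sequence[GroundTruthMetabolite],
    phenotypes: Optional[Sequence[PhenotypeProfile]] = None,
    marker_manifest: Optional[Dict[str, Dict[str, float]]] = None,
) -> StudyDataset:
    """Simulate the full acquisition campaign.

    Extracts are assigned to batches in contiguous subject blocks; each
    (mode, method) sequence interleaves pooled-QC injections at the
    configured interval.  The QC pool is the deterministic mean of all
    extracts' expected spectra (it inherits the batch factor of its
    position) with small injection noise.  All randomness derives from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    if phenotypes is None:
        phenotypes = generate_phenotypes(design.n_subjects, rng)
    phenotypes = list(phenotypes)
    if len(phenotypes) != design.n_subjects:
        raise ValueError("phenotype list does not match n_subjects")
    index = _PanelIndex(panel)

    # per-extract dilution and batch layout
    specimens = [
        (p, r)
        for p in phenotypes
        for r in range(1, design.replicates_per_subject + 1)
    ]
    dilution = {
        f"{p.subject_id}_r{r}": float(10.0 ** rng.normal(0.0, design.dilution_sd))
        for p, r in specimens
    }
    batch_factors = {
        f"B{b + 1}": float(10.0 ** rng.normal(0.0, design.batch_sd))
        for b in range(design.n_batches)
    }
    block = int(np.ceil(len(specimens) / design.n_batches))
    batch_of = {
        f"{p.subject_id}_r{r}": f"B{min(i // block, design.n_batches - 1) + 1}"
        for i, (p, r) in enumerate(specimens)
    }

    # deterministic pooled-QC expectation per (mode, metabolite)
    pooled: Dict[str, np.ndarray] = {}
    for mode in MODES:
        per_specimen = np.array(
            [
                [
                    met.expected_intensity(p, mode) * dilution[f"{p.subject_id}_r{r}"]
                    for met in panel
                ]
                for p, r in specimens
            ]
        )
        pooled[mode] = per_specimen.mean(axis=0)

    peak_lists: List[PeakList] = []
    for p, r in specimens:
        spec = f"{p.subject_id}_r{r}"
        peak_lists.extend(
            simulate_sample(
                p, panel, design, rng,
                replicate_index=r,
                dilution=dilution[spec],
                batch=batch_of[spec],
                batch_factor=batch_factors[batch_of[spec]],
                _index=index,
            )
        )

    # QC injections per (mode, method) sequence
    n_analytical = len(specimens)
    for mode in MODES:
        for method in design.mass_ranges:
            lo, hi = design.mass_ranges[method]
            for q, pos in enumerate(qc_schedule(n_analytical, design.qc_interval)):
                anchor = specimens[min(pos, n_analytical - 1)]
                batch = batch_of[f"{anchor[0].subject_id}_r{anchor[1]}"]
                qc_id = f"QC{q + 1:02d}"
                mzs, intens = [], []
                for met, iso, base in zip(index.panel, index.ion[mode], pooled[mode]):
                    noisy = (
                        base
                        * batch_factors[batch]
                        * 10.0 ** rng.normal(0.0, design.qc_noise_sd)
                    )
                    for mz_t, rel in iso:
                        inten = noisy * rel
                        if inten < design.lod:
                            continue
                        mz_obs = mz_t * (
                            1.0 + rng.normal(0.0, design.ppm_noise_sd) * 1e-6
                        )
                        if lo <= mz_obs <= hi:
                            mzs.append(float(mz_obs))
                            intens.append(float(inten))
                peak_lists.append(
                    PeakList(
                        sample_id=f"{qc_id}_r0_{mode[:3]}_{method}",
                        subject_id=qc_id,
                        replicate_index=0,
                        mode=mode,
                        method=method,
                        batch=batch,
                        mz=np.asarray(mzs),
                        intensity=np.asarray(intens),
                        is_qc=True,
                    )
                )

    manifest: Dict[str, object] = {
        "markers": marker_manifest or {},
        "dilution": dilution,
        "batch_factors": batch_factors,
        "batches": batch_of,
        "panel": [
            {
                "db_id": met.db_id,
                "formula": format_formula(met.formula),
                "base_log_intensity": met.base_log_intensity,
                "mode_efficiency": dict(met.mode_efficiency),
                "adduct": {m: a.name for m, a in met.adduct.items()},
                "detection_prob": met.detection_prob,
                "effects": dict(met.effects),
            }
            for met in panel
        ],
        "design": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(design).items()
        },
    }
    return StudyDataset(
        peak_lists=peak_lists,
        phenotypes=phenotypes_to_frame(phenotypes),
        panel=list(panel),
        manifest=manifest,
    )
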