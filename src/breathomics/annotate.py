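"""Exact-mass annotation against reference lists, and m/z recalibration.

A feature is putatively identified when some (reference formula, adduct)
combination reproduces its m/z within the ppm tolerance and — where an
observed isotope pattern is available — the simulated fine structure fits
below the score cut-off.  Reference lists are plain TSV exports
(formula, name, db_id, main_class), the shape of an HMDB/HBDB download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adducts import AdductRule, ppm_error, theoretical_mz
from .formula import ChemicalFormula, format_formula, parse_formula
from .isotopes import IsotopePattern, isotope_fit_score, isotope_pattern
from .peaks import PeakList

DEFAULT_TOL_PPM = 1.0
DEFAULT_MAX_ISOTOPE_SCORE = 300.0


@dataclass(frozen=True)
class ReferenceRecord:
    """One row of an annotation list."""

    formula: ChemicalFormula
    putative_name: str
    db_id: str
    main_class: str


@dataclass(frozen=True)
class AnnotationHit:
    """A (feature, reference record, adduct) link that passed both gates."""

    feature_id: str
    record: ReferenceRecord
    adduct: AdductRule
    mz_observed: float
    mz_theoretical: float
    ppm_error: float
    isotope_score: float  # NaN when no observed pattern was available


def read_reference_list(path) -> List[ReferenceRecord]:
    """Read a TSV annotation list with columns formula, name, db_id, main_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"formula", "name", "db_id", "main_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference list missing columns: {sorted(missing)}")
    records = [
        ReferenceRecord(
            formula=parse_formula(f),
            putative_name=str(n),
            db_id=str(i),
            main_class=str(c),
        )
        for f, n, i, c in zip(
            df["formula"], df["name"], df["db_id"], df["main_class"]
        )
    ]
    ids = [r.db_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("db_id values must be unique within a reference list")
    return records


def write_reference_list(records: Sequence[ReferenceRecord], path) -> None:
    pd.DataFrame(
        {
            "formula": [format_formula(r.formula) for r in records],
            "name": [r.putative_name for r in records],
            "db_id": [r.db_id for r in records],
            "main_class": [r.main_class for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def recalibrate(
    peaks: PeakList,
    calibrants: Sequence[Tuple[ChemicalFormula, AdductRule]],
    window_ppm: float = 5.0,
) -> Tuple[PeakList, Dict[str, object]]:
    """Linear m/z recalibration against a local calibrant list.

    Calibrants matched within ``window_ppm`` anchor a least-squares linear
    map observed -> theoretical (offset only when a single calibrant
    matches), which is then applied to every peak.  Returns the corrected
    peak list and a report with matched calibrants and their post-correction
    residuals in ppm.
    """
    matches: List[Tuple[float, float]] = []  # (observed, theoretical)
    used: List[str] = []
    for formula, adduct in calibrants:
        if adduct.polarity != peaks.mode:
            continue
        mz_t = theoretical_mz(formula, adduct)
        j = peaks.nearest_peak(mz_t, window_ppm)
        if j is not None:
            matches.append((float(peaks.mz[j]), mz_t))
            used.append(f"{format_formula(formula)} {adduct.name}")
    if not matches:
        raise ValueError("no calibrant matched within the search window")
    obs = np.array([m[0] for m in matches])
    theo = np.array([m[1] for m in matches])
    if len(matches) == 1:
        slope, offset = 1.0, float(theo[0] - obs[0])
    else:
        slope, offset = np.polyfit(obs, theo, 1)
    corrected = peaks.with_mz(slope * peaks.mz + offset)
    residuals = (slope * obs + offset - theo) / theo * 1e6
    report = {
        "n_calibrants_matched": len(matches),
        "calibrants": used,
        "slope": float(slope),
        "offset_da": float(offset),
        "residual_ppm": [float(r) for r in residuals],
        "rms_residual_ppm": float(np.sqrt(np.mean(residuals**2))),
    }
    return corrected, report


def _candidate_index(
    reference: Sequence[ReferenceRecord], adducts: Sequence[AdductRule], mode: str
) -> Tuple[np.ndarray, List[Tuple[ReferenceRecord, AdductRule]]]:
    pairs = [
        (rec, ad)
        for rec in reference
        for ad in adducts
        if ad.polarity == mode
    ]
    mzs = np.array([theoretical_mz(rec.formula, ad) for rec, ad in pairs])
    order = np.argsort(mzs)
    return mzs[order], [pairs[i] for i in order]


def annotate_features(
    features: pd.DataFrame,
    reference: Sequence[ReferenceRecord],
    adducts: Sequence[AdductRule],
    tol_ppm: float = DEFAULT_TOL_PPM,
    max_score: float = DEFAULT_MAX_ISOTOPE_SCORE,
    patterns: Optional[Mapping[str, IsotopePattern]] = None,
    resolving_power: float = 488_000.0,
    pattern_floor: float = 1e-3,
) -> List[AnnotationHit]:
    """Annotate features (columns feature_id, mz, mode) against a reference.

    Emits one hit per (feature, record, adduct) with |ppm error| < tol_ppm
    and, when an observed isotope pattern is supplied for the feature,
    fine-structure score < max_score.  Hits are ordered per feature by
    (|ppm error|, isotope score); features without a hit simply yield none.
    The result is deterministic and independent of reference-list order.
    """
    if not len(reference):
        raise ValueError("empty reference list")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    patterns = patterns or {}
    hits: List[AnnotationHit] = []
    for mode in sorted(features["mode"].unique()):
        cand_mz, cand = _candidate_index(reference, adducts, mode)
        if cand_mz.size == 0:
            continue
        sub = features[features["mode"] == mode]
        for fid, mz_obs in zip(sub["feature_id"], sub["mz"]):
            lo = np.searchsorted(cand_mz, mz_obs * (1 - tol_ppm * 1e-6))
            hi = np.searchsorted(cand_mz, mz_obs * (1 + tol_ppm * 1e-6))
            feat_hits = []
            for k in range(lo, hi):
                rec, ad = cand[k]
                err = ppm_error(mz_obs, cand_mz[k])
                if abs(err) >= tol_ppm:
                    continue
                score = float("nan")
                obs_pat = patterns.get(fid)
                if obs_pat is not None:
                    theo_pat = isotope_pattern(
                        rec.formula,
                        resolving_power=resolving_power,
                        abundance_floor=pattern_floor,
                        adduct=ad,
                    )
                    try:
                        score = isotope_fit_score(obs_pat, theo_pat)
                    except ValueError:
                        continue  # base peak itself unmatched
                    if score >= max_score:
                        continue
                feat_hits.append(
                    AnnotationHit(
                        feature_id=str(fid),
                        record=rec,
                        adduct=ad,
                        mz_observed=float(mz_obs),
                        mz_theoretical=float(cand_mz[k]),
                        ppm_error=float(err),
                        isotope_score=score,
                    )
                )
            feat_hits.sort(
                key=lambda h: (
                    abs(h.ppm_error),
                    0.0 if np.isnan(h.isotope_score) else h.isotope_score,
                    h.record.db_id,
                )
            )
            hits.extend(feat_hits)
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as the TSV-ready output table."""
    return pd.DataFrame(
        {
            "feature_id": [h.feature_id for h in hits],
            "formula": [format_formula(h.record.formula) for h in hits],
            "adduct": [h.adduct.name for h in hits],
            "mz_observed": [h.mz_observed for h in hits],
            "mz_theoretical": [h.mz_theoretical for h in hits],
            "ppm_error": [h.ppm_error for h in hits],
            "isotope_score": [h.isotope_score for h in hits],
            "name": [h.record.putative_name for h in hits],
            "db_id": [h.record.db_id for h in hits],
            "main_class": [h.record.main_class for h in hits],
        }
    )
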