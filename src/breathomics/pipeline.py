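"""End-to-end workflow: raw peak lists to consensus statistics.

The stage order is fixed: recalibrate -> bin into per-(mode, method)
feature tables -> annotate (mass + fine structure) -> de-isotope -> PQN
against the pooled QCs -> batch correction -> combine methods and
deduplicate -> merge ionisation modes -> 2-of-3 replicate consensus ->
prevalence filters -> imputation and median normalization for the
statistics.  :func:`process_cohort` runs it in memory;
:func:`run_pipeline` wraps it with file I/O and per-stage provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as bio
from .adducts import adducts_for_mode
from .annotate import AnnotationHit, ReferenceRecord, annotate_features, hits_to_frame, recalibrate
from .coverage import class_coverage, coverage_frame, filter_classes
from .isotopes import IsotopePattern
from .peaks import PeakList
from .preprocess import (
    FeatureTable,
    attach_annotations,
    batch_correct,
    build_feature_table,
    concat_tables,
    deduplicate,
    impute_missing,
    log_pareto,
    median_normalize,
    merge_modes,
    pqn_normalize,
    prevalence_filter,
    qc_rsd_report,
    remove_isotopologue_satellites,
    replicate_consensus,
)
from .stats import ConsensusThresholds, consensus

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run."""

    tol_ppm: float = 1.0
    max_isotope_score: float = 300.0
    calibrant_window_ppm: float = 5.0
    # fine-structure evidence is only demanded where it is measurable:
    # satellites below the detection limit cannot veto an annotation
    score_floor_rel: float = 0.05
    score_min_intensity: float = 1e8
    lod: float = 1e6
    impute_fraction: float = 0.2
    prevalence_first: float = 0.05
    prevalence_second: float = 0.15
    pqn_reference: str = "qc_median"
    grouping: str = "gender"
    thresholds: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    n_components: int = 5
    n_trees: int = 500
    seed: int = 0
    deisotope: bool = True
    stage_prevalence_second: bool = True

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


def observed_patterns(
    table: FeatureTable,
    min_intensity: float = 1e8,
    window: float = 4.5,
) -> Dict[str, IsotopePattern]:
    """Observed isotope patterns from the binned features themselves.

    For every feature intense enough for its satellites to clear the
    detection limit, neighbouring features up to ``window`` Da above it
    form the observed pattern, with abundances relative to the feature's
    own mean intensity.  Weak features get no pattern — annotation then
    rests on mass accuracy alone.
    """
    mz = table.features["mz"].to_numpy()
    mean_int = table.values.mean(axis=1).to_numpy()
    order = np.argsort(mz)
    mz_sorted = mz[order]
    int_sorted = mean_int[order]
    fids = table.features.index.to_numpy()[order]
    out: Dict[str, IsotopePattern] = {}
    for i, fid in enumerate(fids):
        if int_sorted[i] < min_intensity:
            continue
        lo = np.searchsorted(mz_sorted, mz_sorted[i] - 1e-3)
        hi = np.searchsorted(mz_sorted, mz_sorted[i] + window)
        peaks = []
        for j in range(lo, hi):
            rel = int_sorted[j] / int_sorted[i]
            if rel > 0:
                peaks.append((float(mz_sorted[j]), float(rel)))
        if peaks:
            out[str(fid)] = IsotopePattern(tuple(peaks))
    return out


def make_groups(
    phenotypes: pd.DataFrame, covariate: str, binary: bool = True
) -> Dict[str, str]:
    """Subject -> group label for a phenotype covariate.

    Binary groupings follow the study's contrasts: gender female/male,
    ``oc_use`` FOC/FnOC (females only), alcohol consumer/none, boolean
    covariates yes/no.  With ``binary=False`` the raw category labels are
    kept (for multi-group ANOVA on diet, activity or alcohol frequency).
    """
    out: Dict[str, str] = {}
    for subject, row in phenotypes.iterrows():
        if covariate == "gender":
            out[subject] = row["gender"]
        elif covariate == "oc_use":
            if row["gender"] != "female":
                continue
            out[subject] = "FOC" if row["oc_use"] else "FnOC"
        elif covariate == "alcohol":
            if binary:
                out[subject] = "none" if row["alcohol"] == "none" else "consumer"
            else:
                out[subject] = row["alcohol"]
        elif covariate in ("smoking", "coffee", "supplements", "allergies"):
            out[subject] = "yes" if row[covariate] else "no"
        elif covariate in ("diet", "activity"):
            if binary:
                ref = "flexitarian" if covariate == "diet" else "regular"
                out[subject] = "ref" if row[covariate] == ref else "other"
            else:
                out[subject] = row[covariate]
        else:
            raise KeyError(f"unknown covariate {covariate!r}")
    return out


@dataclass
class CohortArtifacts:
    """Everything :func:`process_cohort` produces, stage by stage."""

    per_mode_method: Dict[Tuple[str, str], FeatureTable]
    hits: List[AnnotationHit]
    merged: FeatureTable
    per_subject: FeatureTable
    table_first_filter: FeatureTable
    table_second_filter: FeatureTable
    stats_ready: FeatureTable
    counts: Dict[str, int]
    reports: Dict[str, object]


def process_cohort(
    peak_lists: Sequence[PeakList],
    reference: Sequence[ReferenceRecord],
    config: Optional[PipelineConfig] = None,
    calibrants: Optional[Sequence] = None,
) -> CohortArtifacts:
    """Run the preprocessing chain on a set of acquisitions."""
    cfg = config or PipelineConfig()
    counts: Dict[str, int] = {"acquisitions": len(peak_lists)}
    reports: Dict[str, object] = {}

    if calibrants:
        recal: List[PeakList] = []
        residuals = []
        for p in peak_lists:
            if len(p) == 0:
                recal.append(p)
                continue
            try:
                corrected, rep = recalibrate(
                    p, calibrants, window_ppm=cfg.calibrant_window_ppm
                )
            except ValueError:
                corrected = p  # nothing matched; leave the axis untouched
                rep = None
            recal.append(corrected)
            if rep:
                residuals.append(rep["rms_residual_ppm"])
        peak_lists = recal
        reports["recalibration_rms_ppm"] = (
            float(np.median(residuals)) if residuals else None
        )

    groups_mm: Dict[Tuple[str, str], List[PeakList]] = {}
    for p in peak_lists:
        groups_mm.setdefault((p.mode, p.method), []).append(p)

    tables: Dict[Tuple[str, str], FeatureTable] = {}
    all_hits: List[AnnotationHit] = []
    for (mode, method), group in sorted(groups_mm.items()):
        table = build_feature_table(group, tol_ppm=cfg.tol_ppm)
        feats = pd.DataFrame(
            {
                "feature_id": table.features.index,
                "mz": table.features["mz"],
                "mode": mode,
            }
        )
        patterns = observed_patterns(table, min_intensity=cfg.score_min_intensity)
        hits = annotate_features(
            feats,
            reference,
            adducts_for_mode(mode),
            tol_ppm=cfg.tol_ppm,
            max_score=cfg.max_isotope_score,
            patterns=patterns,
            pattern_floor=cfg.score_floor_rel,
        )
        table = attach_annotations(table, hits)
        if cfg.deisotope:
            table = remove_isotopologue_satellites(table, tol_ppm=2 * cfg.tol_ppm)
        table, pqn_rep = pqn_normalize(table, reference=cfg.pqn_reference)
        table, batch_rep = batch_correct(table)
        tables[(mode, method)] = table
        all_hits.extend(hits)
        counts[f"features_{mode}_{method}"] = table.n_features
        reports[f"pqn_{mode}_{method}"] = pqn_rep.to_dict()
        reports[f"batch_{mode}_{method}"] = batch_rep.to_dict()
        try:
            reports[f"qc_rsd_{mode}_{method}"] = qc_rsd_report(table).to_dict()
        except ValueError:
            pass

    per_mode: Dict[str, FeatureTable] = {}
    for mode in sorted({m for m, _ in tables}):
        mode_tables = [tables[k] for k in sorted(tables) if k[0] == mode]
        combined = concat_tables(mode_tables)
        per_mode[mode] = deduplicate(combined)
        counts[f"features_{mode}"] = per_mode[mode].n_features

    if len(per_mode) == 2:
        merged = merge_modes(per_mode["positive"], per_mode["negative"])
    else:
        merged = next(iter(per_mode.values()))
    merged = deduplicate(merged)
    counts["features_merged"] = merged.n_features

    per_subject = replicate_consensus(merged)
    counts["subjects"] = per_subject.n_samples

    first = prevalence_filter(per_subject, cfg.prevalence_first)
    counts["features_first_filter"] = first.n_features
    if cfg.stage_prevalence_second:
        second = prevalence_filter(first, cfg.prevalence_second)
    else:
        second = first
    counts["features_second_filter"] = second.n_features

    stats_ready = median_normalize(
        impute_missing(second, lod=cfg.lod, fraction=cfg.impute_fraction)
    )
    return CohortArtifacts(
        per_mode_method=tables,
        hits=all_hits,
        merged=merged,
        per_subject=per_subject,
        table_first_filter=first,
        table_second_filter=second,
        stats_ready=stats_ready,
        counts=counts,
        reports=reports,
    )


def run_pipeline(
    peak_lists: Sequence[PeakList],
    reference: Sequence[ReferenceRecord],
    phenotypes: pd.DataFrame,
    outdir,
    config: Optional[PipelineConfig] = None,
    calibrants: Optional[Sequence] = None,
) -> CohortArtifacts:
    """File-emitting wrapper: runs :func:`process_cohort`, the consensus
    statistics for the configured grouping, and the class-coverage report,
    writing every stage output plus a provenance record to ``outdir``."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    chash = bio.config_hash(cfg_dict)

    art = process_cohort(peak_lists, reference, cfg, calibrants=calibrants)
    bio.write_feature_table(art.merged, outdir / "features_merged.tsv")
    bio.write_feature_table(art.per_subject, outdir / "features_per_subject.tsv")
    bio.write_feature_table(
        art.table_second_filter, outdir / "features_filtered.tsv"
    )
    hits_to_frame(art.hits).to_csv(
        outdir / "annotation_hits.tsv", sep="\t", index=False
    )

    groups = make_groups(phenotypes, cfg.grouping)
    cols = [c for c in art.stats_ready.values.columns if c in groups]
    stats_table = art.stats_ready.subset_samples(cols)
    bio.write_stats_export(stats_table, groups, outdir / "stats_export.tsv")
    result = consensus(
        stats_table,
        groups,
        thresholds=cfg.thresholds,
        n_components=cfg.n_components,
        n_trees=cfg.n_trees,
        seed=cfg.seed,
    )
    result.volcano.table.to_csv(outdir / "volcano.tsv", sep="\t")
    result.plsda.vip.to_frame().to_csv(outdir / "vip.tsv", sep="\t")
    result.rf.importance.to_frame().to_csv(outdir / "rf_importance.tsv", sep="\t")
    result.consensus.to_csv(outdir / "consensus.tsv", sep="\t")
    bio.write_json(
        {
            "config_hash": chash,
            "venn": result.venn,
            "set_sizes": {k: len(v) for k, v in result.sets.items()},
            "rf_oob_error": result.rf.oob_error,
            "plsda_r2y": result.plsda.r2y,
            "plsda_q2y": result.plsda.q2y,
        },
        outdir / "consensus_summary.json",
    )

    cov = filter_classes(
        class_coverage(art.table_second_filter, reference), min_share=0.02
    )
    coverage_frame(cov).to_csv(outdir / "class_coverage.tsv", sep="\t", index=False)

    bio.write_json(
        {
            "config": cfg_dict,
            "config_hash": chash,
            "counts": art.counts,
            "reports": {
                k: v for k, v in art.reports.items() if not k.startswith("pqn_")
            },
        },
        outdir / "provenance.json",
    )
    art.reports["consensus"] = result
    return art
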