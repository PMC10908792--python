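"""Feature-table construction, normalization, merging and filtering.

The stages here turn per-acquisition peak lists into the per-subject
feature table the statistics run on, in a fixed order: build (per mode and
method) -> PQN against the pooled QCs -> batch correction -> mode merge ->
deduplication -> 2-of-3 replicate consensus -> prevalence filters ->
(for statistics) imputation, median normalization and log/Pareto scaling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import AnnotationHit
from .formula import format_formula
from .peaks import PeakList

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "mz", "formula", "name", "db_id", "main_class",
    "adduct", "mode", "method", "ppm_error", "isotope_score",
]
SAMPLE_COLUMNS = ["subject_id", "replicate_index", "batch", "is_qc"]


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with metadata on both axes.

    ``values`` is indexed by feature_id with one column per sample
    (specimen or QC injection); 0 means "not detected". ``features`` and
    ``samples`` carry the per-axis metadata and share the respective index.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.features.index):
            raise ValueError("values and features must share the feature index")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns must match the samples index")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")

    @property
    def n_features(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.features.copy(), self.samples.copy()
        )

    def subset_features(self, index) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[index], self.features.loc[index], self.samples
        )

    def subset_samples(self, cols: Sequence[str]) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            self.values[cols], self.features, self.samples.loc[cols]
        )

    def qc_columns(self) -> List[str]:
        return list(self.samples.index[self.samples["is_qc"].astype(bool)])

    def analytical_columns(self) -> List[str]:
        return list(self.samples.index[~self.samples["is_qc"].astype(bool)])


@dataclass
class NormalizationReport:
    """Per-sample and per-batch scale factors plus QC dispersion summary."""

    method: str
    sample_factors: Dict[str, float] = field(default_factory=dict)
    batch_factors: Dict[str, float] = field(default_factory=dict)
    qc_rsd: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "method": self.method,
            "sample_factors": self.sample_factors,
            "batch_factors": self.batch_factors,
            "qc_rsd": self.qc_rsd,
        }


def build_feature_table(
    peak_lists: Sequence[PeakList],
    tol_ppm: float = 1.0,
) -> FeatureTable:
    """Bin peaks from co-modal acquisitions into one features x samples table.

    All peak lists must share mode and method.  Peaks are pooled, sorted,
    and split into bins wherever the gap to the previous peak exceeds the
    ppm tolerance; a bin becomes a feature with intensity-weighted mean m/z
    and one column per acquisition (co-binned peaks of one acquisition are
    summed).  Columns are keyed by specimen (subject + replicate).  When
    annotation ``hits`` for the resulting feature ids are supplied via
    :func:`attach_annotations` the features gain formula keys.
    """
    if not peak_lists:
        raise ValueError("no peak lists given")
    modes = {p.mode for p in peak_lists}
    methods = {p.method for p in peak_lists}
    if len(modes) != 1 or len(methods) != 1:
        raise ValueError("build_feature_table expects a single (mode, method) group")
    mode, method = modes.pop(), methods.pop()
    cols = [p.specimen for p in peak_lists]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate sample ids in peak-list group")

    all_mz = np.concatenate([p.mz for p in peak_lists]) if peak_lists else np.empty(0)
    all_int = np.concatenate([p.intensity for p in peak_lists])
    all_col = np.concatenate(
        [np.full(len(p), i, dtype=int) for i, p in enumerate(peak_lists)]
    )
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_col = all_mz[order], all_int[order], all_col[order]

    # gap-based single-linkage binning at the ppm tolerance
    if all_mz.size:
        gaps = np.diff(all_mz) > all_mz[1:] * tol_ppm * 1e-6
        bin_id = np.concatenate([[0], np.cumsum(gaps)])
        n_bins = int(bin_id[-1]) + 1
    else:
        bin_id = np.empty(0, dtype=int)
        n_bins = 0

    mat = np.zeros((n_bins, len(peak_lists)))
    np.add.at(mat, (bin_id, all_col), all_int)
    mz_centroid = np.bincount(bin_id, weights=all_mz * all_int, minlength=n_bins)
    mz_centroid = np.divide(
        mz_centroid, np.bincount(bin_id, weights=all_int, minlength=n_bins),
        out=np.zeros(n_bins), where=np.bincount(bin_id, minlength=n_bins) > 0,
    )

    fids = [f"{mode[:3]}_{method}_{i:05d}" for i in range(n_bins)]
    values = pd.DataFrame(mat, index=fids, columns=cols)
    features = pd.DataFrame(
        {
            "mz": mz_centroid,
            "formula": "", "name": "", "db_id": "", "main_class": "",
            "adduct": "", "mode": mode, "method": method,
            "ppm_error": np.nan, "isotope_score": np.nan,
        },
        index=fids,
    )
    samples = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in peak_lists],
            "replicate_index": [p.replicate_index for p in peak_lists],
            "batch": [p.batch for p in peak_lists],
            "is_qc": [p.is_qc for p in peak_lists],
        },
        index=pd.Index(cols),
    )
    return FeatureTable(values, features, samples)


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Stack feature tables that share the same sample columns (used to
    combine the two mass-range methods of one ionisation mode)."""
    if not tables:
        raise ValueError("no tables to concatenate")
    cols = list(tables[0].values.columns)
    for t in tables[1:]:
        if set(t.values.columns) != set(cols):
            raise ValueError("tables must cover the same sample set")
    values = pd.concat([t.values[cols] for t in tables])
    features = pd.concat([t.features for t in tables])
    return FeatureTable(values, features, tables[0].samples.loc[cols])


def attach_annotations(
    table: FeatureTable, hits: Sequence[AnnotationHit]
) -> FeatureTable:
    """Write each feature's top-ranked hit into the feature metadata."""
    out = table.copy()
    seen = set()
    for h in hits:  # hits are ordered best-first per feature
        if h.feature_id in seen or h.feature_id not in out.features.index:
            continue
        seen.add(h.feature_id)
        out.features.loc[h.feature_id, "formula"] = format_formula(h.record.formula)
        out.features.loc[h.feature_id, "name"] = h.record.putative_name
        out.features.loc[h.feature_id, "db_id"] = h.record.db_id
        out.features.loc[h.feature_id, "main_class"] = h.record.main_class
        out.features.loc[h.feature_id, "adduct"] = h.adduct.name
        out.features.loc[h.feature_id, "ppm_error"] = h.ppm_error
        out.features.loc[h.feature_id, "isotope_score"] = h.isotope_score
    return out


def remove_isotopologue_satellites(
    table: FeatureTable, tol_ppm: float = 2.0, max_offset: float = 4.5
) -> FeatureTable:
    """Drop unannotated features that sit at an annotated feature's
    isotopologue positions with lower total intensity (de-isotoping)."""
    from .adducts import adducts_for_mode
    from .formula import parse_formula
    from .isotopes import isotope_pattern

    annotated = table.features.index[table.features["formula"] != ""]
    totals = table.values.sum(axis=1)
    drop = set()
    adduct_by_name = {
        a.name: a
        for mode in ("positive", "negative")
        for a in adducts_for_mode(mode)
    }
    mz = table.features["mz"]
    for fid in annotated:
        ad = adduct_by_name.get(table.features.loc[fid, "adduct"])
        if ad is None:
            continue
        pat = isotope_pattern(
            parse_formula(table.features.loc[fid, "formula"]), adduct=ad
        )
        base = pat.base_mz
        for mz_t, rel in pat.peaks:
            if mz_t == base:
                continue
            near = mz.index[
                (np.abs(mz - mz_t) <= mz_t * tol_ppm * 1e-6)
                & (table.features["formula"] == "")
            ]
            for g in near:
                if totals[g] < totals[fid]:
                    drop.add(g)
    if drop:
        logger.info("de-isotoping removed %d satellite features", len(drop))
    keep = [f for f in table.features.index if f not in drop]
    return table.subset_features(keep)


def pqn_normalize(
    table: FeatureTable,
    reference: Union[str, np.ndarray, pd.Series] = "qc_median",
    min_shared: int = 10,
) -> Tuple[FeatureTable, NormalizationReport]:
    """Probabilistic quotient normalization.

    The reference spectrum is the feature-wise median over the pooled-QC
    columns (``"qc_median"``, the default), the median over all samples
    (``"overall_median"``), or an explicit vector.  Each sample is divided
    by the median of its value/reference quotients over features nonzero in
    both; this removes per-extract dilution exactly when dilution is a
    scalar multiple.
    """
    if isinstance(reference, str):
        if reference == "qc_median":
            qcs = table.qc_columns()
            if not qcs:
                raise ValueError("no QC columns for qc_median PQN reference")
            ref = table.values[qcs].median(axis=1)
        elif reference == "overall_median":
            ref = table.values.median(axis=1)
        else:
            raise ValueError(f"unknown PQN reference {reference!r}")
    else:
        ref = pd.Series(np.asarray(reference, dtype=float), index=table.values.index)

    out = table.copy()
    report = NormalizationReport(method="pqn")
    ref_nz = ref > 0
    for col in out.values.columns:
        v = out.values[col]
        shared = ref_nz & (v > 0)
        if int(shared.sum()) < min_shared:
            raise ValueError(
                f"sample {col!r} shares only {int(shared.sum())} nonzero "
                f"features with the PQN reference (need >= {min_shared})"
            )
        factor = float(np.median(v[shared] / ref[shared]))
        out.values[col] = v / factor
        report.sample_factors[col] = factor
    return out, report


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its nonzero median equals the global median of
    sample medians (the customary row-wise median normalization)."""
    out = table.copy()
    medians = {}
    for col in out.values.columns:
        v = out.values[col]
        nz = v[v > 0]
        if nz.empty:
            raise ValueError(f"sample {col!r} has no nonzero values")
        medians[col] = float(np.median(nz))
    target = float(np.median(list(medians.values())))
    for col in out.values.columns:
        out.values[col] = out.values[col] * (target / medians[col])
    return out


def batch_correct(
    table: FeatureTable, batches: Optional[Mapping[str, str]] = None
) -> Tuple[FeatureTable, NormalizationReport]:
    """Divide out per-batch multiplicative factors anchored on the QCs.

    A batch's factor is the median of its QC intensities over the median of
    all QC intensities; a batch without QCs falls back to its analytical
    sample median (with a warning).
    """
    out = table.copy()
    if batches is not None:
        batch_of = {s: batches[s] for s in out.samples.index}
    else:
        batch_of = dict(out.samples["batch"])
    report = NormalizationReport(method="batch_qc_median")

    qc_cols = [c for c in out.values.columns if out.samples.loc[c, "is_qc"]]
    all_qc = out.values[qc_cols].to_numpy().ravel() if qc_cols else np.empty(0)
    all_qc = all_qc[all_qc > 0]
    global_scale = float(np.median(all_qc)) if all_qc.size else None

    for batch in sorted(set(batch_of.values())):
        cols = [c for c in out.values.columns if batch_of[c] == batch]
        bqc = [c for c in cols if out.samples.loc[c, "is_qc"]]
        if bqc and global_scale is not None:
            v = out.values[bqc].to_numpy().ravel()
            v = v[v > 0]
            factor = float(np.median(v)) / global_scale
        else:
            warnings.warn(
                f"batch {batch!r} has no QC sample; falling back to its "
                "sample median", stacklevel=2,
            )
            v = out.values[cols].to_numpy().ravel()
            v = v[v > 0]
            all_v = out.values.to_numpy().ravel()
            all_v = all_v[all_v > 0]
            factor = float(np.median(v)) / float(np.median(all_v))
        out.values[cols] = out.values[cols] / factor
        report.batch_factors[batch] = factor
    return out, report


def merge_modes(
    table_pos: FeatureTable, table_neg: FeatureTable
) -> FeatureTable:
    """Merge positive- and negative-mode tables into one.

    For a formula annotated in both modes, the mode in which it was
    detected (nonzero) in more samples wins; ties go to the mode with the
    larger summed intensity.  Formulas or unannotated features present in
    one mode only pass through.  The chosen mode is recorded per feature.
    """
    if set(table_pos.values.columns) != set(table_neg.values.columns):
        raise ValueError("mode tables must cover the same sample set")
    cols = list(table_pos.values.columns)
    neg = FeatureTable(
        table_neg.values[cols], table_neg.features, table_neg.samples.loc[cols]
    )
    overlap = set(neg.features.index) & set(table_pos.features.index)
    if overlap:  # disambiguate colliding feature ids before stacking
        renamer = {f: f + ".neg" for f in overlap}
        neg = FeatureTable(
            neg.values.rename(index=renamer),
            neg.features.rename(index=renamer),
            neg.samples,
        )

    pos_by_formula = {
        f: fid
        for fid, f in table_pos.features["formula"].items()
        if f
    }
    neg_by_formula = {
        f: fid
        for fid, f in neg.features["formula"].items()
        if f
    }
    drop_pos, drop_neg = set(), set()
    for formula in sorted(set(pos_by_formula) & set(neg_by_formula)):
        fid_p, fid_n = pos_by_formula[formula], neg_by_formula[formula]
        n_p = int((table_pos.values.loc[fid_p] > 0).sum())
        n_n = int((neg.values.loc[fid_n] > 0).sum())
        if n_p > n_n:
            drop_neg.add(fid_n)
        elif n_n > n_p:
            drop_pos.add(fid_p)
        else:
            tot_p = float(table_pos.values.loc[fid_p].sum())
            tot_n = float(neg.values.loc[fid_n].sum())
            # tie on counts: larger total intensity wins (positive on exact tie)
            if tot_p >= tot_n:
                drop_neg.add(fid_n)
            else:
                drop_pos.add(fid_p)

    keep_p = [f for f in table_pos.features.index if f not in drop_pos]
    keep_n = [f for f in neg.features.index if f not in drop_neg]
    values = pd.concat([table_pos.values.loc[keep_p], neg.values.loc[keep_n]])
    features = pd.concat([table_pos.features.loc[keep_p], neg.features.loc[keep_n]])
    samples = table_pos.samples.copy()
    return FeatureTable(values, features, samples)


def merge_modes_bruteforce(
    table_pos: FeatureTable, table_neg: FeatureTable
) -> FeatureTable:
    """Reference implementation of :func:`merge_modes` by direct enumeration
    (kept separate so the two can be compared in tests)."""
    if set(table_pos.values.columns) != set(table_neg.values.columns):
        raise ValueError("mode tables must cover the same sample set")
    cols = list(table_pos.values.columns)
    rows_v, rows_f, row_ids = [], [], []
    for suffix, (table, other) in (
        ("", (table_pos, table_neg)),
        (".neg", (table_neg, table_pos)),
    ):
        for fid in table.features.index:
            formula = table.features.loc[fid, "formula"]
            if formula:
                match = [
                    g
                    for g in other.features.index
                    if other.features.loc[g, "formula"] == formula
                ]
                if match:
                    g = match[0]
                    mine = (table.values.loc[fid, cols] > 0).sum()
                    theirs = (other.values.loc[g, cols] > 0).sum()
                    if mine < theirs:
                        continue
                    if mine == theirs:
                        tot_m = table.values.loc[fid, cols].sum()
                        tot_t = other.values.loc[g, cols].sum()
                        if tot_m < tot_t:
                            continue
                        if tot_m == tot_t and table is table_neg:
                            continue  # exact tie resolved to positive
            rows_v.append(table.values.loc[fid, cols])
            rows_f.append(table.features.loc[fid])
            row_ids.append(fid + suffix if fid in other.features.index else fid)
    values = pd.DataFrame(np.array([r.to_numpy() for r in rows_v]),
                          index=row_ids, columns=cols)
    features = pd.DataFrame(rows_f)
    features.index = pd.Index(row_ids)
    return FeatureTable(values, features, table_pos.samples.loc[cols])


def deduplicate(table: FeatureTable) -> FeatureTable:
    """Collapse duplicate formulas (two-method overlap, residual adduct
    rows) keeping, per formula, the row with the largest total intensity."""
    totals = table.values.sum(axis=1)
    keep: List[str] = []
    best: Dict[str, str] = {}
    for fid in table.features.index:
        formula = table.features.loc[fid, "formula"]
        if not formula:
            keep.append(fid)
            continue
        cur = best.get(formula)
        if cur is None or totals[fid] > totals[cur]:
            best[formula] = fid
    dropped = [
        fid
        for fid in table.features.index
        if table.features.loc[fid, "formula"] and best[table.features.loc[fid, "formula"]] != fid
    ]
    if dropped:
        logger.info("deduplicate removed %d duplicate rows", len(dropped))
    keep.extend(best.values())
    keep_ordered = [f for f in table.features.index if f in set(keep)]
    return table.subset_features(keep_ordered)


def replicate_consensus(
    table: FeatureTable, min_detected: int = 2
) -> FeatureTable:
    """Reduce replicate columns to one column per subject.

    A feature counts as detected for a subject only when nonzero in at
    least ``min_detected`` of the replicates; the retained intensity is the
    mean of the nonzero replicate values, otherwise 0 ("not detected").
    QC columns are dropped here — they have served normalization.
    """
    analytical = table.analytical_columns()
    sub = table.samples.loc[analytical]
    subjects = list(dict.fromkeys(sub["subject_id"]))
    for s in subjects:
        if int((sub["subject_id"] == s).sum()) < min_detected:
            raise ValueError(f"subject {s!r} has fewer than {min_detected} replicates")
    mat = np.zeros((table.n_features, len(subjects)))
    for j, s in enumerate(subjects):
        cols = list(sub.index[sub["subject_id"] == s])
        block = table.values[cols].to_numpy()
        nz = block > 0
        count = nz.sum(axis=1)
        mean_nz = np.divide(
            block.sum(axis=1), count, out=np.zeros(len(block)), where=count > 0
        )
        mat[:, j] = np.where(count >= min_detected, mean_nz, 0.0)
    values = pd.DataFrame(mat, index=table.values.index, columns=subjects)
    samples = pd.DataFrame(
        {
            "subject_id": subjects,
            "replicate_index": 0,
            "batch": "",
            "is_qc": False,
        },
        index=pd.Index(subjects),
    )
    return FeatureTable(values, table.features.copy(), samples)


def prevalence_filter(table: FeatureTable, min_fraction: float) -> FeatureTable:
    """Keep features detected in at least ceil(min_fraction x n_samples)
    of the (subject-level) columns."""
    if not (0 <= min_fraction <= 1):
        raise ValueError("min_fraction must be in [0, 1]")
    threshold = math.ceil(min_fraction * table.n_samples)
    counts = (table.values > 0).sum(axis=1)
    keep = table.values.index[counts >= threshold]
    logger.info(
        "prevalence filter (%.0f%%, >= %d of %d): %d -> %d features",
        100 * min_fraction, threshold, table.n_samples,
        table.n_features, len(keep),
    )
    return table.subset_features(keep)


def impute_missing(
    table: FeatureTable, lod: float = 1e6, fraction: float = 0.2
) -> FeatureTable:
    """Replace every zero by ``lod * fraction`` (the 1/5-of-LOD rule)."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    out = table.copy()
    out.values = out.values.mask(out.values == 0, lod * fraction)
    return out


def log_pareto(table: FeatureTable, base: float = 10.0) -> FeatureTable:
    """Log-transform, then Pareto-scale each feature (centre and divide by
    the square root of its standard deviation; constant features stay at 0)."""
    if (table.values.to_numpy() <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    out = table.copy()
    logged = np.log(table.values.to_numpy()) / np.log(base)
    centred = logged - logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    scale = np.sqrt(sd)
    scaled = np.divide(centred, scale, out=centred.copy(), where=scale > 0)
    out.values = pd.DataFrame(
        scaled, index=table.values.index, columns=table.values.columns
    )
    return out


def qc_rsd_report(table: FeatureTable) -> NormalizationReport:
    """Per-feature relative standard deviation across the QC injections."""
    qcs = table.qc_columns()
    if len(qcs) < 2:
        raise ValueError("need at least 2 QC columns for an RSD report")
    block = table.values[qcs].to_numpy()
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsd = np.where(mean > 0, sd / mean, np.nan)
    rsd = rsd[np.isfinite(rsd)]
    report = NormalizationReport(method="qc_rsd")
    report.qc_rsd = {
        "n_qc": float(len(qcs)),
        "median": float(np.median(rsd)) if rsd.size else float("nan"),
        "q25": float(np.percentile(rsd, 25)) if rsd.size else float("nan"),
        "q75": float(np.percentile(rsd, 75)) if rsd.size else float("nan"),
    }
    return report
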