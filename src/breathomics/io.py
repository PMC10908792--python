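"""TSV/CSV/JSON serialization for peak lists, tables and reports.

The canonical dialect is tab-separated, dot-decimal UTF-8 with LF line
endings; numeric values are written at 10 significant digits so that a
write/read round trip reproduces the in-memory data exactly at that
precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .peaks import PeakList
from .preprocess import FEATURE_COLUMNS, FeatureTable

PathLike = Union[str, Path]

_PEAK_HEADER_KEYS = [
    "sample_id", "subject_id", "replicate_index", "mode", "method",
    "batch", "is_qc",
]


def write_peak_list(peaks: PeakList, path: PathLike) -> None:
    """One acquisition as TSV: '# key<TAB>value' metadata then mz/intensity."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key in _PEAK_HEADER_KEYS:
            fh.write(f"# {key}\t{getattr(peaks, key)}\n")
        fh.write("mz\tintensity\n")
        for mz, inten in zip(peaks.mz, peaks.intensity):
            fh.write(f"{mz:.10g}\t{inten:.10g}\n")


def read_peak_list(path: PathLike) -> PeakList:
    """Parse a peak-list TSV written by :func:`write_peak_list`."""
    path = Path(path)
    meta: Dict[str, str] = {}
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed metadata line in {path}: {line!r}")
                meta[parts[0]] = parts[1]
            elif line == "mz\tintensity":
                continue
            elif line:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed peak line in {path}: {line!r}")
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(
                        f"non-numeric peak value in {path}: {line!r}"
                    ) from exc
    missing = [k for k in _PEAK_HEADER_KEYS if k not in meta]
    if missing:
        raise ValueError(f"peak list {path} missing metadata: {missing}")
    mz = np.array([r[0] for r in rows])
    inten = np.array([r[1] for r in rows])
    return PeakList(
        sample_id=meta["sample_id"],
        subject_id=meta["subject_id"],
        replicate_index=int(meta["replicate_index"]),
        mode=meta["mode"],
        method=meta["method"],
        batch=meta["batch"],
        mz=mz,
        intensity=inten,
        is_qc=meta["is_qc"] == "True",
    )


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    """Feature table as TSV (features in rows, samples in columns) plus a
    ``<stem>.samples.tsv`` sidecar with the sample metadata."""
    path = Path(path)
    df = pd.concat([table.features[FEATURE_COLUMNS], table.values], axis=1)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
    side = path.with_name(path.stem + ".samples.tsv")
    samples = table.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(side, sep="\t", lineterminator="\n")


def read_feature_table(path: PathLike) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    features = df[FEATURE_COLUMNS].copy()
    for col in ("formula", "name", "db_id", "main_class", "adduct", "mode", "method"):
        features[col] = features[col].fillna("").astype(str)
    values = df.drop(columns=FEATURE_COLUMNS).astype(float)
    side = path.with_name(path.stem + ".samples.tsv")
    samples = pd.read_csv(side, sep="\t", index_col="sample_id")
    samples.index = samples.index.astype(str)
    samples["batch"] = samples["batch"].fillna("").astype(str)
    values.columns = values.columns.astype(str)
    return FeatureTable(values, features, samples)


def write_stats_export(
    table: FeatureTable, groups: Mapping[str, str], path: PathLike
) -> None:
    """Statistics export: samples in columns with a second header row of
    group labels (the layout expected by common metabolomics suites)."""
    path = Path(path)
    cols = [c for c in table.values.columns if c in groups]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(cols) + "\n")
        fh.write("group\t" + "\t".join(groups[c] for c in cols) + "\n")
        for fid, row in table.values[cols].iterrows():
            fh.write(fid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_json(data: Mapping, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: PathLike) -> Dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg
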