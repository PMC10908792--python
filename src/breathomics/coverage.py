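"""Chemical-class coverage of the detected metabolome.

Answers "how much of each chemical main class that the reference database
lists could we actually see in breath?": per class, the number of distinct
reference entries hit by an annotated feature over the number of entries
the database holds, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import pandas as pd

from .annotate import ReferenceRecord
from .preprocess import FeatureTable


@dataclass(frozen=True)
class ClassCoverage:
    main_class: str
    detected: int
    potential: int

    @property
    def coverage(self) -> float:
        """Percent of the class's reference entries detected."""
        return 100.0 * self.detected / self.potential if self.potential else 0.0


def class_coverage(
    detected: Union[FeatureTable, Sequence[str]],
    reference: Sequence[ReferenceRecord],
) -> List[ClassCoverage]:
    """Per-class detected/potential counts, sorted by coverage descending.

    ``detected`` is either an annotated feature table (its features'
    ``db_id`` column names the hits; a feature contributes only through its
    top-ranked annotation) or an iterable of detected db_ids.  Each class's
    potential is the number of reference entries carrying that label.
    """
    if not reference:
        raise ValueError("empty reference list")
    if any(not r.main_class for r in reference):
        raise ValueError("reference records must carry main_class labels")
    if isinstance(detected, FeatureTable):
        ids = [i for i in detected.features["db_id"] if i]
    else:
        ids = [str(i) for i in detected]
    by_id = {r.db_id: r for r in reference}
    detected_ids = {i for i in ids if i in by_id}

    classes = sorted({r.main_class for r in reference})
    out = []
    for cls in classes:
        potential = sum(1 for r in reference if r.main_class == cls)
        det = sum(1 for i in detected_ids if by_id[i].main_class == cls)
        out.append(ClassCoverage(cls, det, potential))
    out.sort(key=lambda c: (-c.coverage, c.main_class))
    return out


def filter_classes(
    coverages: Sequence[ClassCoverage], min_share: float = 0.02
) -> List[ClassCoverage]:
    """Keep classes holding at least ``min_share`` of all detected hits
    (boundary inclusive)."""
    total = sum(c.detected for c in coverages)
    if total == 0:
        return []
    return [c for c in coverages if c.detected >= min_share * total]


def coverage_frame(coverages: Sequence[ClassCoverage]) -> pd.DataFrame:
    """Coverage report as the TSV-ready table."""
    return pd.DataFrame(
        {
            "main_class": [c.main_class for c in coverages],
            "detected": [c.detected for c in coverages],
            "potential": [c.potential for c in coverages],
            "coverage_pct": [c.coverage for c in coverages],
        }
    )
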