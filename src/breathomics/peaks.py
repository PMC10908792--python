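"""The raw acquisition unit: one centroided peak list with its metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Acquisition methods and their m/z windows (Da). The two windows overlap
#: between 95 and 300 m/z, which is what makes method deduplication necessary.
METHOD_WINDOWS = {
    "ultra-small": (65.0, 300.0),
    "small": (95.0, 1500.0),
}


@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs from a single acquisition.

    ``subject_id`` is the volunteer code, or a QC tag (``is_qc=True``) for
    pooled quality-control injections. ``mode`` is the ionisation polarity,
    ``method`` the mass-range method ("ultra-small": 65-300 m/z,
    "small": 95-1500 m/z).
    """

    sample_id: str
    subject_id: str
    replicate_index: int
    mode: str
    method: str
    batch: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_qc: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity <= 0):
            raise ValueError("peak intensities must be positive")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown ionisation mode {self.mode!r}")
        if self.method not in METHOD_WINDOWS:
            raise ValueError(f"unknown acquisition method {self.method!r}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def specimen(self) -> str:
        """Key identifying the physical extract: subject + replicate."""
        return f"{self.subject_id}_r{self.replicate_index}"

    def with_mz(self, new_mz: np.ndarray) -> "PeakList":
        """Copy with a corrected m/z axis (used by recalibration)."""
        return replace(self, mz=np.asarray(new_mz, dtype=float),
                       intensity=self.intensity.copy())

    def nearest_peak(self, mz: float, tol_ppm: float) -> Optional[int]:
        """Index of the closest peak within ``tol_ppm`` of ``mz``, or None."""
        if len(self) == 0:
            return None
        j = int(np.argmin(np.abs(self.mz - mz)))
        if abs(self.mz[j] - mz) / mz * 1e6 <= tol_ppm:
            return j
        return None
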