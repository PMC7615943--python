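"""Intensity discretization into Ng gray levels.

Two equal-width uniform quantizers are provided, matching the two
conventions compared across radiomics toolkits:

* **GUQ** (global uniform quantizer / "fixed bin width"): one binning of
  a cohort-global HU range shared by every case and scan, so equal HU
  values always map to equal labels.
* **IUQ** (individual uniform quantizer / "fixed bin count"): equal-width
  bins fitted to each ROI's own min–max range, making the labels exactly
  invariant under positive affine transforms of the intensities.

Labels are 1-based; the maximum intensity maps to level Ng (closed top
bin) so no phantom Ng+1 level appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError
from .preprocess import ThresholdWindow

GUQ = "GUQ"
IUQ = "IUQ"


@dataclass(frozen=True)
class QuantizationSpec:
    """Full description of one discretization arm."""

    method: str = GUQ
    levels: int = 128
    global_range_hu: Optional[tuple[float, float]] = None
    threshold: ThresholdWindow = field(default_factory=ThresholdWindow)

    def __post_init__(self) -> None:
        if self.method not in (GUQ, IUQ):
            raise ValueError(f"method must be {GUQ!r} or {IUQ!r}, got {self.method!r}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.global_range_hu is not None:
            lo, hi = self.global_range_hu
            if not lo < hi:
                raise ValueError(f"global range requires lo < hi, got ({lo}, {hi})")

    def resolve_global_range(self) -> tuple[float, float]:
        """The HU range anchoring the GUQ binning.

        Defaults to the threshold window when thresholding is enabled;
        otherwise an explicit cohort-global range must have been set
        (the pipeline computes it in a first pass over all in-mask voxels).
        """
        if self.global_range_hu is not None:
            return self.global_range_hu
        if self.threshold.enabled:
            return (self.threshold.lo_hu, self.threshold.hi_hu)
        raise ConfigError(
            "GUQ without a threshold window needs an explicit global_range_hu"
        )

    def with_global_range(self, lo: float, hi: float) -> "QuantizationSpec":
        return replace(self, global_range_hu=(float(lo), float(hi)))

    @property
    def arm_id(self) -> str:
        return f"{self.method}{self.levels}_{self.threshold.label}"


@dataclass
class QuantizedROI:
    """Discretized in-ROI intensities, aligned with the ROI's voxel order."""

    labels: np.ndarray  # int labels in 1..levels
    indices: np.ndarray  # (N, 3) voxel indices, lexicographic
    spec: QuantizationSpec
    n_clamped: int = 0  # GUQ only: intensities outside the global range

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (
            self.labels.min() < 1 or self.labels.max() > self.spec.levels
        ):
            raise ValueError("labels must lie in 1..levels")

    @property
    def ng_eff(self) -> int:
        """Highest occupied level (<= the nominal Ng)."""
        return int(self.labels.max()) if self.labels.size else 0


def quantize_iuq(intensities: np.ndarray, ng: int) -> np.ndarray:
    """Fixed-bin-count labels: Ng equal-width bins over this ROI's min–max.

    label(x) = min(floor(Ng * (x - m) / (M - m)) + 1, Ng); a constant
    ROI (M == m) maps everything to level 1.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot quantize an empty intensity list")
    if ng < 2:
        raise ValueError(f"levels must be >= 2, got {ng}")
    m, big = x.min(), x.max()
    if big == m:
        return np.ones(x.shape, dtype=np.int64)
    labels = np.floor(ng * (x - m) / (big - m)).astype(np.int64) + 1
    return np.minimum(labels, ng)


def quantize_guq(
    intensities: np.ndarray, ng: int, global_range_hu: tuple[float, float]
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width labels over a shared global HU range.

    Bin width W = (hi - lo) / Ng; label(x) = clamp(floor((x - lo)/W) + 1,
    1, Ng). Returns the labels and the count of intensities that fell
    outside the global range and were clamped.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot quantize an empty intensity list")
    if ng < 2:
        raise ValueError(f"levels must be >= 2, got {ng}")
    lo, hi = global_range_hu
    if not lo < hi:
        raise ValueError(f"global range requires lo < hi, got ({lo}, {hi})")
    width = (hi - lo) / ng
    raw = np.floor((x - lo) / width).astype(np.int64) + 1
    labels = np.clip(raw, 1, ng)
    n_clamped = int(np.count_nonzero((x < lo) | (x > hi)))
    return labels, n_clamped


def guq_bin_width(ng: int, global_range_hu: tuple[float, float]) -> float:
    """The equal bin width W = (hi - lo) / Ng in HU."""
    lo, hi = global_range_hu
    return (hi - lo) / ng


def quantize(
    intensities: np.ndarray, indices: np.ndarray, spec: QuantizationSpec
) -> QuantizedROI:
    """Dispatch to the quantizer named by ``spec`` and package the result."""
    if spec.method == IUQ:
        labels = quantize_iuq(intensities, spec.levels)
        n_clamped = 0
    else:
        labels, n_clamped = quantize_guq(
            intensities, spec.levels, spec.resolve_global_range()
        )
    return QuantizedROI(labels=labels, indices=indices, spec=spec, n_clamped=n_clamped)
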