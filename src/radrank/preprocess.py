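"""ROI pre-processing: HU threshold re-segmentation and optional resampling.

The threshold window (default −200..300 HU) removes voxels whose CT
number falls outside the soft-tissue range of interest — typically
air-filled or bony voxels swept into a manually outlined gross tumor
volume. Thresholding happens *before* quantization, and the re-segmented
mask defines the intensity range seen by the individual (per-ROI)
quantizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, EmptyROIError
from .image_io import ImageVolume, ROIMask

#: Re-segmented ROIs smaller than this are flagged with a warning, not dropped.
MIN_ROI_VOXELS = 10


@dataclass(frozen=True)
class ThresholdWindow:
    """An inclusive HU window applied to the ROI before quantization."""

    lo_hu: float = -200.0
    hi_hu: float = 300.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and not self.lo_hu < self.hi_hu:
            raise ValueError(
                f"threshold window requires lo_hu < hi_hu, got "
                f"[{self.lo_hu}, {self.hi_hu}]"
            )

    @property
    def label(self) -> str:
        return "threshold" if self.enabled else "no_threshold"


def apply_threshold(
    volume: ImageVolume,
    mask: ROIMask,
    window: ThresholdWindow,
    case_hint: str = "",
) -> ROIMask:
    """Intersect the mask with ``lo_hu <= HU <= hi_hu`` (both bounds inclusive).

    A disabled window returns the mask unchanged. The result is never
    larger than the input and the operation is idempotent. An empty
    result raises :class:`EmptyROIError` because no feature can be
    extracted from it.
    """
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"{case_hint or 'ROI'}: mask shape {mask.shape} != volume shape "
            f"{volume.shape}"
        )
    if mask.n_voxels == 0:
        raise EmptyROIError(f"{case_hint or 'ROI'}: input mask is empty")
    if not window.enabled:
        return mask
    keep = mask.data & (volume.data >= window.lo_hu) & (volume.data <= window.hi_hu)
    n = int(keep.sum())
    if n == 0:
        raise EmptyROIError(
            f"{case_hint or 'ROI'}: no voxels remain inside "
            f"[{window.lo_hu}, {window.hi_hu}] HU"
        )
    if n < MIN_ROI_VOXELS:
        warnings.warn(
            f"{case_hint or 'ROI'}: only {n} voxels remain after threshold "
            f"re-segmentation (< {MIN_ROI_VOXELS}); texture statistics will be "
            "unstable",
            stacklevel=2,
        )
    return ROIMask(data=keep, spacing=mask.spacing, origin=mask.origin)


def extract_roi(
    volume: ImageVolume, mask: ROIMask, case_hint: str = ""
) -> tuple[np.ndarray, np.ndarray]:
    """Return in-mask intensities and voxel indices, ordered lexicographically.

    The fixed (x, y, z)-lexicographic order makes every downstream
    quantization and matrix build reproducible bit-for-bit.
    """
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"{case_hint or 'ROI'}: mask shape {mask.shape} != volume shape "
            f"{volume.shape}"
        )
    idx = np.argwhere(mask.data)  # C order == lexicographic in (x, y, z)
    if idx.shape[0] == 0:
        raise EmptyROIError(f"{case_hint or 'ROI'}: mask is empty")
    intensities = volume.data[tuple(idx.T)]
    return intensities, idx


def resample_isotropic(
    volume: ImageVolume, mask: ROIMask, target_spacing_mm: float
) -> tuple[ImageVolume, ROIMask]:
    """Resample volume (trilinear) and mask (nearest neighbor) to an isotropic grid.

    The output grid covers the original physical extent. Intended for
    real scans with anisotropic slices; phantom cohorts are generated
    isotropic so resampling is off by default in the pipeline.
    """
    if target_spacing_mm <= 0:
        raise ValueError(f"target spacing must be > 0, got {target_spacing_mm}")

    def _resample(data: np.ndarray, spacing, origin, interpolator):
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
        )
        img.SetSpacing(tuple(spacing))
        img.SetOrigin(tuple(origin))
        # keep every output voxel center inside the input center domain so
        # linear interpolation never extrapolates the padding value
        new_size = [
            max(1, int(np.floor((n - 1) * s / target_spacing_mm + 1e-9)) + 1)
            for n, s in zip(data.shape, spacing)
        ]
        res = sitk.Resample(
            img,
            new_size,
            sitk.Transform(),
            interpolator,
            img.GetOrigin(),
            (target_spacing_mm,) * 3,
            img.GetDirection(),
            0.0,
            img.GetPixelID(),
        )
        out = np.ascontiguousarray(np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0)))
        return out

    new_vol = _resample(
        volume.data.astype(np.float64), volume.spacing, volume.origin, sitk.sitkLinear
    )
    new_mask = _resample(
        mask.data.astype(np.uint8), mask.spacing, mask.origin, sitk.sitkNearestNeighbor
    )
    spacing = (target_spacing_mm,) * 3
    return (
        ImageVolume(data=new_vol, spacing=spacing, origin=volume.origin),
        ROIMask(data=new_mask, spacing=spacing, origin=mask.origin),
    )
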