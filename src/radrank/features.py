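"""The 43 scalar texture features shared across radiomics toolkits.

The registry is partitioned into 3 first-order, 9 GLCM, 13 GLRLM,
13 GLSZM, and 5 NGTDM features. First-order moments are computed on the
raw (unquantized) HU values inside the re-segmented ROI; all matrix
features use the 1-based quantized labels as the gray-level indices in
their i/j weights.

Conventions pinned here (each pinned by an oracle test):

* Entropy uses log base 2 with 0·log 0 := 0.
* GLCM Sum Average is Σ p(i,j)·(i+j)/2, which for a symmetric GLCM
  equals the marginal gray-level mean.
* GLCM Variance is Σ p(i,j)·(i−μ)² with μ = Σ p(i,j)·i the joint
  gray-level mean.
* GLV/RLV (and GLV/ZSV) are the variances of gray level and run length
  (zone size) over the run (zone) probability distribution.
* NGTDM Coarseness is capped at 1e6 when its denominator vanishes
  (constant ROI); NGTDM Strength is 0 when Σ s_i = 0.
* Degenerate inputs (no valid pairs/runs/zones, constant marginals)
  yield NaN, never a silent zero: NaN values are excluded pairwise by
  the rank-correlation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyROIError
from .image_io import Cohort, ImageVolume, ROIMask
from .preprocess import apply_threshold, extract_roi
from .quantize import QuantizationSpec, QuantizedROI, quantize
from .texture import AVERAGED, MERGED, TextureMatrixSet, build_matrix_set, labels_volume

COARSENESS_CAP = 1.0e6

FIRST_ORDER_NAMES = ("Variance", "Skewness", "Kurtosis")
GLCM_NAMES = tuple(
    f"GLCM {n}"
    for n in (
        "Energy",
        "Contrast",
        "Entropy",
        "Homogeneity",
        "Correlation",
        "Sum Average",
        "Variance",
        "Autocorrelation",
        "Dissimilarity",
    )
)
GLRLM_NAMES = tuple(
    f"GLRLM {n}"
    for n in (
        "SRE",
        "LRE",
        "GLN",
        "RLN",
        "RP",
        "LGRE",
        "HGRE",
        "SRLGE",
        "SRHGE",
        "LRLGE",
        "LRHGE",
        "GLV",
        "RLV",
    )
)
GLSZM_NAMES = tuple(
    f"GLSZM {n}"
    for n in (
        "SZE",
        "LZE",
        "GLN",
        "ZSN",
        "ZP",
        "LGZE",
        "HGZE",
        "SZLGE",
        "SZHGE",
        "LZLGE",
        "LZHGE",
        "GLV",
        "ZSV",
    )
)
NGTDM_NAMES = tuple(
    f"NGTDM {n}" for n in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
)

#: Ordered (name, class) registry of the 43 common features.
FEATURE_REGISTRY: tuple[tuple[str, str], ...] = (
    tuple((n, "first-order") for n in FIRST_ORDER_NAMES)
    + tuple((n, "GLCM") for n in GLCM_NAMES)
    + tuple((n, "GLRLM") for n in GLRLM_NAMES)
    + tuple((n, "GLSZM") for n in GLSZM_NAMES)
    + tuple((n, "NGTDM") for n in NGTDM_NAMES)
)

FEATURE_NAMES: tuple[str, ...] = tuple(n for n, _ in FEATURE_REGISTRY)
FEATURE_CLASSES: tuple[str, ...] = ("first-order", "GLCM", "GLRLM", "GLSZM", "NGTDM")


def registry_class_counts() -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, cls in FEATURE_REGISTRY:
        counts[cls] = counts.get(cls, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# first order


def first_order(intensities: np.ndarray) -> dict[str, float]:
    """Population variance, skewness (m3/m2^1.5), and Pearson kurtosis (m4/m2²).

    Kurtosis is non-excess (a normal distribution gives 3). A constant
    input returns (0, 0, 0) by convention.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise EmptyROIError("first-order features need at least one intensity")
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return {
        "Variance": float(m2),
        "Skewness": float(m3 / m2**1.5),
        "Kurtosis": float(m4 / m2**2),
    }


# ---------------------------------------------------------------------------
# GLCM


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    if p.sum() <= 0:
        return {name: float("nan") for name in GLCM_NAMES}
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt((px * (i - mux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i - muy) ** 2).sum()))
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    if sigx > 0 and sigy > 0:
        correlation = float(((I * J * p).sum() - mux * muy) / (sigx * sigy))
    else:
        correlation = float("nan")
    mu = float((I * p).sum())  # joint gray-level mean; == mux for symmetric p
    return {
        "GLCM Energy": float((p**2).sum()),
        "GLCM Contrast": float(((I - J) ** 2 * p).sum()),
        "GLCM Entropy": entropy,
        "GLCM Homogeneity": float((p / (1.0 + np.abs(I - J))).sum()),
        "GLCM Correlation": correlation,
        "GLCM Sum Average": float(((I + J) / 2.0 * p).sum()),
        "GLCM Variance": float(((I - mu) ** 2 * p).sum()),
        "GLCM Autocorrelation": float((I * J * p).sum()),
        "GLCM Dissimilarity": float((np.abs(I - J) * p).sum()),
    }


def glcm_features(glcm: np.ndarray, dialect: str = MERGED) -> dict[str, float]:
    """The 9 GLCM features.

    merged: computed on the single direction-merged normalized matrix.
    averaged: computed per direction and arithmetically averaged; a NaN
    in any direction propagates (degenerate directions flag the value).
    """
    if dialect == MERGED:
        return _glcm_single(np.asarray(glcm, dtype=np.float64))
    stack = np.asarray(glcm, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    per_dir = [_glcm_single(m) for m in stack]
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# run-length / size-zone shared core

_RL_SUFFIXES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
    "GLV",
    "RLV",
)
_SZ_SUFFIXES = (
    "SZE",
    "LZE",
    "GLN",
    "ZSN",
    "ZP",
    "LGZE",
    "HGZE",
    "SZLGE",
    "SZHGE",
    "LZLGE",
    "LZHGE",
    "GLV",
    "ZSV",
)


def _size_distribution_features(counts: np.ndarray, n_slots: float) -> list[float]:
    """The 13 features shared (in functional form) by GLRLM and GLSZM.

    ``counts[i-1, j-1]`` counts runs/zones of gray level i with length/size
    j; ``n_slots`` is the voxel total that the emphasis ratio (RP/ZP) is
    taken against.
    """
    c = np.asarray(counts, dtype=np.float64)
    n = c.sum()
    if n <= 0:
        return [float("nan")] * 13
    ng, jmax = c.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, jmax + 1, dtype=np.float64)[None, :]
    gi = c.sum(axis=1)  # per-gray-level totals
    rj = c.sum(axis=0)  # per-length totals
    ivec = i.ravel()
    jvec = j.ravel()
    mu_i = (gi * ivec).sum() / n
    mu_j = (rj * jvec).sum() / n
    return [
        float((c / j**2).sum() / n),  # SRE / SZE
        float((c * j**2).sum() / n),  # LRE / LZE
        float((gi**2).sum() / n),  # GLN
        float((rj**2).sum() / n),  # RLN / ZSN
        float(n / n_slots),  # RP / ZP
        float((c / i**2).sum() / n),  # LGRE / LGZE
        float((c * i**2).sum() / n),  # HGRE / HGZE
        float((c / (i**2 * j**2)).sum() / n),  # SRLGE / SZLGE
        float((c * i**2 / j**2).sum() / n),  # SRHGE / SZHGE
        float((c * j**2 / i**2).sum() / n),  # LRLGE / LZLGE
        float((c * i**2 * j**2).sum() / n),  # LRHGE / LZHGE
        float((gi * (ivec - mu_i) ** 2).sum() / n),  # GLV
        float((rj * (jvec - mu_j) ** 2).sum() / n),  # RLV / ZSV
    ]


def glrlm_features(
    glrlm, n_voxels: int, n_directions: int = 1
) -> dict[str, float]:
    """The 13 GLRLM features.

    For a direction-merged count matrix pass ``n_directions=13`` so Run
    Percentage stays in (0, 1] (runs from all 13 directions cover
    13·n_voxels voxel slots). For a per-direction list the features are
    computed per direction (each with ``n_directions=1``) and averaged.
    """
    if isinstance(glrlm, (list, tuple)):
        per_dir = [
            _size_distribution_features(m, float(n_voxels)) for m in glrlm
        ]
        vals = [float(np.mean([d[k] for d in per_dir])) for k in range(13)]
    else:
        vals = _size_distribution_features(glrlm, float(n_voxels) * n_directions)
    return dict(zip(GLRLM_NAMES, vals))


def glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 13 GLSZM features (zone analogues of the run-length set)."""
    vals = _size_distribution_features(glszm, float(n_voxels))
    return dict(zip(GLSZM_NAMES, vals))


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(
    n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray
) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength.

    With fewer than two occupied gray levels the Contrast and Busyness
    denominators vanish; both are NaN in that case.
    """
    n_i = np.asarray(n_i, dtype=np.float64)
    p_i = np.asarray(p_i, dtype=np.float64)
    s_i = np.asarray(s_i, dtype=np.float64)
    total = n_i.sum()
    if total <= 0:
        return {name: float("nan") for name in NGTDM_NAMES}
    levels = np.arange(1, len(n_i) + 1, dtype=np.float64)
    occ = p_i > 0
    ngp = int(occ.sum())
    io = levels[occ]
    po = p_i[occ]
    so = s_i[occ]

    den = float((p_i * s_i).sum())
    coarseness = COARSENESS_CAP if den == 0.0 else min(1.0 / den, COARSENESS_CAP)

    if ngp >= 2:
        dij2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            (po[:, None] * po[None, :] * dij2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / total)
        )
        bus_den = float(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum())
        busyness = float(den / bus_den) if bus_den > 0 else float("nan")
    else:
        contrast = float("nan")
        busyness = float("nan")

    dij = np.abs(io[:, None] - io[None, :])
    num = dij * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
    pden = po[:, None] + po[None, :]
    complexity = float((num / pden).sum() / total)

    s_sum = float(s_i.sum())
    if s_sum > 0:
        strength = float(((po[:, None] + po[None, :]) * dij**2).sum() / s_sum)
    else:
        strength = 0.0

    return {
        "NGTDM Coarseness": float(coarseness),
        "NGTDM Contrast": contrast,
        "NGTDM Busyness": busyness,
        "NGTDM Complexity": complexity,
        "NGTDM Strength": strength,
    }


# ---------------------------------------------------------------------------
# end-to-end extraction


@dataclass
class FeatureVector:
    """All 43 features for one (case, scan) under one extraction arm."""

    values: dict[str, float]
    case_id: str = ""
    scan_id: str = ""
    arm_id: str = ""
    dialect: str = MERGED
    n_voxels: int = 0
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("feature vector keys must match the canonical registry")

    @property
    def degenerate(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.values.items() if not np.isfinite(v))


@dataclass
class FeatureTable:
    """cases × 43 features for one extraction arm (quantizer + dialect)."""

    frame: pd.DataFrame  # MultiIndex (case_id, scan_id); columns FEATURE_NAMES
    arm_id: str = ""
    dialect: str = MERGED
    spec: Optional[QuantizationSpec] = None

    def select_scan(self, scan_id: str) -> "FeatureTable":
        sub = self.frame.xs(scan_id, level="scan_id", drop_level=True)
        return FeatureTable(
            frame=sub.copy(), arm_id=self.arm_id, dialect=self.dialect, spec=self.spec
        )

    @property
    def case_ids(self) -> list[str]:
        idx = self.frame.index
        if isinstance(idx, pd.MultiIndex):
            return list(idx.get_level_values("case_id").unique())
        return list(idx)


_BOUNDS_TOL = 1e-9
_UNIT_INTERVAL_FEATURES = (
    "GLCM Energy",
    "GLCM Homogeneity",
    "GLRLM SRE",
    "GLRLM RP",
    "GLSZM SZE",
    "GLSZM ZP",
)


def _check_bounds(values: dict[str, float], hint: str) -> None:
    for name in _UNIT_INTERVAL_FEATURES:
        v = values[name]
        if np.isfinite(v) and not (0.0 < v <= 1.0 + _BOUNDS_TOL):
            raise RuntimeError(f"{hint}: {name}={v} outside (0, 1]")
    corr = values["GLCM Correlation"]
    if np.isfinite(corr) and abs(corr) > 1.0 + _BOUNDS_TOL:
        raise RuntimeError(f"{hint}: GLCM Correlation={corr} outside [-1, 1]")


def extract_feature_vector(
    volume: ImageVolume,
    mask: ROIMask,
    spec: QuantizationSpec,
    dialect: str = MERGED,
    case_id: str = "",
    scan_id: str = "",
    distance: int = 1,
) -> FeatureVector:
    """Threshold → ROI extraction → first order on raw HU → quantize →
    texture matrices → all 43 features. Deterministic for fixed inputs."""
    hint = f"case {case_id!r} scan {scan_id!r}" if case_id else "ROI"
    roi_mask = apply_threshold(volume, mask, spec.threshold, case_hint=hint)
    intensities, indices = extract_roi(volume, roi_mask, case_hint=hint)
    values: dict[str, float] = dict.fromkeys(FEATURE_NAMES, float("nan"))
    values.update(first_order(intensities))

    qroi: QuantizedROI = quantize(intensities, indices, spec)
    if qroi.n_clamped:
        warnings.warn(
            f"{hint}: {qroi.n_clamped} intensities outside the GUQ global "
            "range were clamped",
            stacklevel=2,
        )
    label_vol = labels_volume(qroi.labels, qroi.indices, volume.shape)
    mats: TextureMatrixSet = build_matrix_set(
        label_vol, spec.levels, dialect=dialect, distance=distance
    )
    values.update(glcm_features(mats.glcm, dialect=dialect))
    n_dirs = mats.n_directions if dialect == MERGED else 1
    values.update(glrlm_features(mats.glrlm, mats.n_voxels, n_directions=n_dirs))
    values.update(glszm_features(mats.glszm, mats.n_voxels))
    values.update(ngtdm_features(*mats.ngtdm))

    ordered = {name: values[name] for name in FEATURE_NAMES}
    _check_bounds(ordered, hint)
    return FeatureVector(
        values=ordered,
        case_id=case_id,
        scan_id=scan_id,
        arm_id=spec.arm_id,
        dialect=dialect,
        n_voxels=mats.n_voxels,
        n_clamped=qroi.n_clamped,
    )


def extract_feature_table(
    cohort: Cohort,
    spec: QuantizationSpec,
    dialect: str = MERGED,
    arm_id: str = "",
    distance: int = 1,
) -> FeatureTable:
    """Extract one arm's feature table over every (case, scan) in the cohort."""
    rows = []
    index = []
    for case in cohort:
        for scan_id, vol, mask in case.scans:
            fv = extract_feature_vector(
                vol,
                mask,
                spec,
                dialect=dialect,
                case_id=case.case_id,
                scan_id=scan_id,
                distance=distance,
            )
            rows.append(fv.values)
            index.append((case.case_id, scan_id))
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["case_id", "scan_id"]),
        columns=list(FEATURE_NAMES),
    )
    return FeatureTable(
        frame=frame,
        arm_id=arm_id or f"{spec.arm_id}_{dialect}",
        dialect=dialect,
        spec=spec,
    )
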