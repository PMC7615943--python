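"""Synthetic test–retest cohorts of lesion-bearing CT-like volumes.

Each case carries an ellipsoidal "gross tumor volume" filled with
spatially correlated texture on a uniform background, mimicking the
structure of public test–retest CT archives: a cohort of patients, each
with one or two scans of the same lesion taken minutes apart. The
second scan adds independent Gaussian HU noise inside the lesion,
standing in for acquisition variability between repeat scans (a free
parameter — it is not an estimate of any real archive's test–retest
variability).

The correlated texture is white Gaussian noise smoothed with a Gaussian
kernel whose standard deviation equals the correlation length, then
re-standardized to zero mean and unit variance. This is simple,
seedable, and sufficient to make cases distinguishable by their texture
features.

Per-case heterogeneity — a uniform offset of the lesion mean HU plus
relative jitter of the texture amplitude and correlation length — keeps
the cohort's rank orderings non-degenerate (a rank correlation over
identical cases would be undefined).

Seeding uses a splittable scheme: every random draw comes from a
``numpy.random.SeedSequence`` spawned from the master seed with the
(case index, stream) pair as the spawn key, so any case can be
regenerated independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError
from .image_io import CaseRecord, Cohort, ImageVolume, ROIMask


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic cohort.

    Defaults produce lesions whose HU values stay inside the −200..300
    window used for threshold re-segmentation, while the one-voxel mask
    dilation ring (emulating manual-outlining slop around the lesion)
    sweeps in background voxels at −800 HU that thresholding removes —
    so the threshold-on and threshold-off arms genuinely differ.
    """

    n_cases: int = 12
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_semiaxes_mm: tuple[float, float, float] = (9.0, 8.0, 7.0)
    background_hu: float = -800.0
    lesion_hu_mean: float = 50.0
    lesion_hu_range: float = 120.0
    texture_correlation_length_mm: float = 3.0
    retest_noise_sd_hu: float = 5.0
    n_scans_per_case: int = 2
    master_seed: int = 0
    case_jitter_hu: float = 30.0  # uniform offset of the per-case lesion mean
    case_variation_frac: float = 0.25  # relative jitter of range and corr. length
    mask_dilation_voxels: int = 1  # contour-slop ring around the true lesion

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid dimensions must be >= 1, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"spacing must be > 0, got {self.voxel_spacing_mm}")
        if any(a <= 0 for a in self.lesion_semiaxes_mm):
            raise ValueError(f"semiaxes must be > 0, got {self.lesion_semiaxes_mm}")
        for a, n, s in zip(
            self.lesion_semiaxes_mm, self.grid_shape, self.voxel_spacing_mm
        ):
            if a >= n * s / 2:
                raise ValueError(
                    f"lesion semiaxis {a} mm does not fit inside half the grid "
                    f"extent ({n * s / 2} mm)"
                )
        if self.lesion_hu_range < 0:
            raise ValueError("lesion_hu_range must be >= 0")
        if self.retest_noise_sd_hu < 0:
            raise ValueError("retest_noise_sd_hu must be >= 0")
        if self.n_scans_per_case not in (1, 2):
            raise ValueError(
                f"n_scans_per_case must be 1 or 2, got {self.n_scans_per_case}"
            )
        if self.texture_correlation_length_mm < 0:
            raise ValueError("texture_correlation_length_mm must be >= 0")
        if not 0 <= self.case_variation_frac < 1:
            raise ValueError("case_variation_frac must lie in [0, 1)")


def _case_rng(master_seed: int, case_index: int, stream: int) -> np.random.Generator:
    """Splittable per-(case, stream) generator; stream 0 = case parameters,
    stream 1+scan = that scan's fields."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(case_index, stream))
    return np.random.default_rng(ss)


def correlated_field(
    grid_shape: tuple[int, int, int],
    correlation_length_mm: float,
    voxel_spacing_mm: tuple[float, float, float],
    seed,
) -> np.ndarray:
    """A zero-mean unit-variance Gaussian random field with the given
    correlation length.

    Realized as Gaussian smoothing of white noise (kernel sd =
    correlation length, converted to voxels per axis) followed by
    re-standardization over all voxels. A correlation length of 0
    yields independent (white) noise. ``seed`` may be an int, a
    SeedSequence, or a Generator.
    """
    if any(n < 1 for n in grid_shape):
        raise ValueError(f"grid dimensions must be >= 1, got {grid_shape}")
    if correlation_length_mm < 0:
        raise ValueError("correlation length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field = rng.standard_normal(grid_shape)
    if correlation_length_mm > 0:
        sigma = [correlation_length_mm / s for s in voxel_spacing_mm]
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    sd = field.std()
    if sd == 0:  # single-voxel grid
        return np.zeros(grid_shape)
    return (field - field.mean()) / sd


def lesion_mask(
    grid_shape: tuple[int, int, int],
    voxel_spacing_mm: tuple[float, float, float],
    center_voxel: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> ROIMask:
    """Binary ellipsoid mask: a voxel is included iff its physical center
    satisfies Σ((x_i − c_i)/a_i)² ≤ 1."""
    for c, n in zip(center_voxel, grid_shape):
        if not 0 <= c < n:
            raise ValueError(f"ellipsoid center {center_voxel} outside grid {grid_shape}")
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(grid_shape, voxel_spacing_mm)],
        indexing="ij",
    )
    q = sum(
        ((x - c * s) / a) ** 2
        for x, c, s, a in zip(coords, center_voxel, voxel_spacing_mm, semiaxes_mm)
    )
    data = q <= 1.0
    if not data.any():
        raise DegenerateGeometryError(
            f"ellipsoid with semiaxes {semiaxes_mm} mm contains no voxel center"
        )
    return ROIMask(data=data, spacing=tuple(voxel_spacing_mm))


def generate_case(spec: PhantomSpec, case_index: int) -> CaseRecord:
    """One synthetic case: textured ellipsoidal lesion on a uniform
    background, with an optional second scan perturbed by retest noise."""
    if not 0 <= case_index < spec.n_cases:
        raise ValueError(f"case_index {case_index} outside 0..{spec.n_cases - 1}")

    prng = _case_rng(spec.master_seed, case_index, 0)
    f = spec.case_variation_frac
    mean_offset = prng.uniform(-spec.case_jitter_hu, spec.case_jitter_hu)
    range_mult = prng.uniform(1 - f, 1 + f)
    length_mult = prng.uniform(1 - f, 1 + f)

    center = tuple((n - 1) / 2 for n in spec.grid_shape)
    lesion = lesion_mask(
        spec.grid_shape, spec.voxel_spacing_mm, center, spec.lesion_semiaxes_mm
    )
    if spec.mask_dilation_voxels > 0:
        roi = ROIMask(
            data=ndimage.binary_dilation(
                lesion.data, iterations=spec.mask_dilation_voxels
            ),
            spacing=lesion.spacing,
        )
    else:
        roi = lesion

    rng1 = _case_rng(spec.master_seed, case_index, 1)
    field = correlated_field(
        spec.grid_shape,
        spec.texture_correlation_length_mm * length_mult,
        spec.voxel_spacing_mm,
        rng1,
    )
    vol1 = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    inside = lesion.data
    vol1[inside] = (
        spec.lesion_hu_mean
        + mean_offset
        + (spec.lesion_hu_range * range_mult / 2.0) * field[inside]
    )

    scans = [
        (
            "scan1",
            ImageVolume(data=vol1, spacing=spec.voxel_spacing_mm),
            roi,
        )
    ]
    if spec.n_scans_per_case == 2:
        vol2 = vol1.copy()
        if spec.retest_noise_sd_hu > 0:
            rng2 = _case_rng(spec.master_seed, case_index, 2)
            vol2[inside] += rng2.normal(
                0.0, spec.retest_noise_sd_hu, size=int(inside.sum())
            )
        scans.append(
            (
                "scan2",
                ImageVolume(data=vol2, spacing=spec.voxel_spacing_mm),
                roi,
            )
        )
    return CaseRecord(case_id=f"case{case_index:03d}", scans=scans)


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """A cohort of ``spec.n_cases`` cases with unique identifiers.

    At least two cases are required because rank correlation over a
    single case is meaningless.
    """
    if spec.n_cases < 2:
        raise ValueError(f"a cohort needs >= 2 cases, got {spec.n_cases}")
    return Cohort(cases=[generate_case(spec, i) for i in range(spec.n_cases)])
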