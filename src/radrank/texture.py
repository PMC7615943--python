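"""Discrete texture matrices built from a quantized ROI in 3D.

Four matrix families are supported:

* **GLCM** — joint distribution of gray-level pairs at a fixed offset,
  accumulated over the 13 unique directions of the 26-neighborhood and
  symmetrized.
* **GLRLM** — counts of maximal collinear runs of equal gray level, per
  direction; voxels outside the (re-segmented) mask break runs.
* **GLSZM** — counts of 26-connected zones of equal gray level
  (direction-free).
* **NGTDM** — per-level occurrence counts, probabilities, and summed
  absolute deviation of each voxel from the mean gray level of its
  in-mask 26-neighborhood.

Two aggregation *dialects* capture the documented difference between
radiomics ecosystems: ``merged`` accumulates counts over all 13
directions into a single matrix before computing features (the MATLAB
toolkit convention); ``averaged`` keeps one matrix per direction and
averages the per-direction feature values (the Pyradiomics convention).
GLSZM and NGTDM are dialect-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy import ndimage

MERGED = "merged"
AVERAGED = "averaged"
DIALECTS = (MERGED, AVERAGED)

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def direction_offsets(distance: int = 1) -> np.ndarray:
    """The 13 unique 3D neighbor offsets (26-neighborhood modulo sign).

    Offsets are kept when their first nonzero component is positive, so
    no offset is the negation of another.
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        first = next(c for c in d if c != 0)
        if first > 0:
            offs.append(d)
    out = np.array(offs, dtype=np.int64) * distance
    assert out.shape == (13, 3)
    return out


def labels_volume(
    labels: np.ndarray, indices: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Scatter ROI labels into a full-grid int volume; 0 marks out-of-mask."""
    vol = np.zeros(grid_shape, dtype=np.int64)
    vol[tuple(np.asarray(indices).T)] = labels
    return vol


def _offset_views(vol: np.ndarray, d: np.ndarray):
    """Paired views of ``vol`` such that a[i] and b[i] are voxels v, v+d."""
    sl_a, sl_b = [], []
    for axis_len, step in zip(vol.shape, d):
        step = int(step)
        if step >= 0:
            sl_a.append(slice(0, axis_len - step))
            sl_b.append(slice(step, axis_len))
        else:
            sl_a.append(slice(-step, axis_len))
            sl_b.append(slice(0, axis_len + step))
    return vol[tuple(sl_a)], vol[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_direction_counts(
    label_vol: np.ndarray, ng: int, distance: int = 1
) -> np.ndarray:
    """Symmetrized co-occurrence count matrices, one per direction: (13, Ng, Ng)."""
    dirs = direction_offsets(distance)
    out = np.zeros((len(dirs), ng, ng), dtype=np.int64)
    for k, d in enumerate(dirs):
        a, b = _offset_views(label_vol, d)
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        flat = (a[both] - 1) * ng + (b[both] - 1)
        counts = np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
        out[k] = counts + counts.T
    return out


def build_glcm(
    label_vol: np.ndarray, ng: int, dialect: str = MERGED, distance: int = 1
):
    """Normalized GLCM.

    merged: one (Ng, Ng) matrix, counts summed over the 13 directions
    then normalized to sum 1. averaged: an (n_dirs, Ng, Ng) stack with
    each direction normalized separately; directions with no valid pair
    are dropped. A ROI with no valid pair in any direction yields an
    all-zero matrix (merged) or an empty stack (averaged) — downstream
    features are then NaN.
    """
    _check_dialect(dialect)
    per_dir = glcm_direction_counts(label_vol, ng, distance)
    if dialect == MERGED:
        total = per_dir.sum(axis=0).astype(np.float64)
        s = total.sum()
        return total / s if s > 0 else total
    mats = []
    for counts in per_dir:
        s = counts.sum()
        if s > 0:
            mats.append(counts.astype(np.float64) / s)
    return np.array(mats) if mats else np.zeros((0, ng, ng))


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_direction_counts(
    label_vol: np.ndarray, ng: int, distance: int = 1
) -> list[np.ndarray]:
    """Run-length count matrices, one (Ng, Rmax_d) matrix per direction.

    A run is a maximal collinear sequence of in-mask voxels sharing one
    label; out-of-mask voxels (label 0) break runs.
    """
    dirs = direction_offsets(distance)
    shape = label_vol.shape
    # zero padding lets the walk stop on label 0 without bounds checks
    pad = distance
    padded = np.zeros([n + 2 * pad for n in shape], dtype=np.int64)
    padded[pad:-pad, pad:-pad, pad:-pad] = label_vol
    plist = padded.tolist()  # nested lists: plain-int indexing in the walk
    out = []
    for d in dirs:
        # run starts: in-mask voxels whose predecessor along -d is absent
        starts = label_vol > 0
        a, b = _offset_views(label_vol, d)  # b = a's successor along d
        # voxel at position of b has predecessor a; mark non-starts there
        same = (a > 0) & (b > 0) & (a == b)
        pred_sl = tuple(
            slice(int(s), axis_len) if int(s) >= 0 else slice(0, axis_len + int(s))
            for axis_len, s in zip(shape, d)
        )
        starts[pred_sl] &= ~same
        dx, dy, dz = (int(c) for c in d)
        runs: dict[tuple[int, int], int] = {}
        xs, ys, zs = np.nonzero(starts)
        for x, y, z in zip(xs.tolist(), ys.tolist(), zs.tolist()):
            x, y, z = x + pad, y + pad, z + pad
            lab = plist[x][y][z]
            length = 1
            x, y, z = x + dx, y + dy, z + dz
            while plist[x][y][z] == lab:
                length += 1
                x, y, z = x + dx, y + dy, z + dz
            key = (lab, length)
            runs[key] = runs.get(key, 0) + 1
        rmax = max((r for _, r in runs), default=1)
        mat = np.zeros((ng, rmax), dtype=np.int64)
        for (lab, r), c in runs.items():
            mat[lab - 1, r - 1] = c
        out.append(mat)
    return out


def build_glrlm(
    label_vol: np.ndarray, ng: int, dialect: str = MERGED, distance: int = 1
):
    """GLRLM counts: merged -> single (Ng, Rmax) matrix summed over the 13
    directions; averaged -> list of per-direction matrices."""
    _check_dialect(dialect)
    per_dir = glrlm_direction_counts(label_vol, ng, distance)
    if dialect == AVERAGED:
        return per_dir
    rmax = max(m.shape[1] for m in per_dir)
    total = np.zeros((ng, rmax), dtype=np.int64)
    for m in per_dir:
        total[:, : m.shape[1]] += m
    return total


# ---------------------------------------------------------------------------
# GLSZM


def build_glszm(label_vol: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone counts: entry (i, s) counts 26-connected zones of level i+1,
    size s+1."""
    zones: dict[tuple[int, int], int] = {}
    for lab in np.unique(label_vol):
        if lab == 0:
            continue
        comp, n_comp = ndimage.label(label_vol == lab, structure=_CONNECTIVITY_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for size in sizes:
            key = (int(lab), int(size))
            zones[key] = zones.get(key, 0) + 1
    zmax = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, zmax), dtype=np.int64)
    for (lab, size), c in zones.items():
        mat[lab - 1, size - 1] = c
    return mat


# ---------------------------------------------------------------------------
# NGTDM


def build_ngtdm(
    label_vol: np.ndarray, ng: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference components (n_i, p_i, s_i).

    Every in-mask voxel with at least one in-mask 26-neighbor contributes
    |i - mean(neighbor labels)| to s_i for its level i. Voxels with no
    in-mask neighbor are excluded entirely; if none contributes, all
    components are zero and dependent features are NaN downstream.
    """
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    in_mask = label_vol > 0
    m = in_mask.astype(np.float64)
    nb_count = ndimage.correlate(m, kernel, mode="constant", cval=0.0)
    nb_sum = ndimage.correlate(label_vol * m, kernel, mode="constant", cval=0.0)
    valid = in_mask & (nb_count > 0.5)
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=np.float64)
    p_i = np.zeros(ng, dtype=np.float64)
    if valid.any():
        lv = label_vol[valid]
        diff = np.abs(lv - nb_sum[valid] / nb_count[valid])
        n_i = np.bincount(lv - 1, minlength=ng)[:ng]
        s_i = np.bincount(lv - 1, weights=diff, minlength=ng)[:ng]
        p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# bundle


@dataclass
class TextureMatrixSet:
    """The four matrix families built from one quantized ROI."""

    glcm: np.ndarray  # merged: (Ng, Ng) normalized; averaged: (n_dirs, Ng, Ng)
    glrlm: object  # merged: (Ng, Rmax) counts; averaged: list of per-dir counts
    glszm: np.ndarray  # (Ng, Zmax) counts
    ngtdm: tuple[np.ndarray, np.ndarray, np.ndarray]  # (n_i, p_i, s_i)
    n_voxels: int
    ng: int
    dialect: str
    n_directions: int = 13


def build_matrix_set(
    label_vol: np.ndarray,
    ng: int,
    dialect: str = MERGED,
    distance: int = 1,
    n_voxels: Optional[int] = None,
) -> TextureMatrixSet:
    """Build all four matrix families from a full-grid label volume."""
    _check_dialect(dialect)
    if n_voxels is None:
        n_voxels = int(np.count_nonzero(label_vol))
    return TextureMatrixSet(
        glcm=build_glcm(label_vol, ng, dialect, distance),
        glrlm=build_glrlm(label_vol, ng, dialect, distance),
        glszm=build_glszm(label_vol, ng),
        ngtdm=build_ngtdm(label_vol, ng),
        n_voxels=n_voxels,
        ng=ng,
        dialect=dialect,
        n_directions=len(direction_offsets(distance)),
    )


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
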