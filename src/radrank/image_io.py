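"""Volumes, masks, cohorts, and their on-disk representations.

In-memory convention
--------------------
All arrays are stored with axis order ``(x, y, z)`` and a voxel-spacing
triple in the same order.  Every direction offset used by the texture
builders follows this single convention, which removes the most common
source of discrepancy between radiomics implementations.

Volumes and masks are read and written as NIfTI-1 (``.nii``, ``.nii.gz``)
or NRRD files; cohorts are described by a CSV manifest with columns
``case_id, scan_id, volume_path, mask_path``; feature tables round-trip
through CSV at 17 significant digits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, FormatError, ManifestError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .features import FeatureTable

MANIFEST_COLUMNS = ("case_id", "scan_id", "volume_path", "mask_path")

Triple = tuple[float, float, float]


def _check_triple(name: str, value) -> Triple:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar image in Hounsfield Units on a regular grid."""

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume payload must be 3D, got {self.data.ndim} dimensions"
            )
        self.spacing = _check_triple("spacing", self.spacing)
        self.origin = _check_triple("origin", self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A binary region-of-interest mask aligned with an :class:`ImageVolume`.

    Any nonzero voxel in the input is treated as foreground and
    normalized to ``True``.
    """

    data: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask payload must be 3D, got {arr.ndim} dimensions")
        self.data = arr != 0
        self.spacing = _check_triple("spacing", self.spacing)
        self.origin = _check_triple("origin", self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class CaseRecord:
    """One patient case: an identifier plus one or two aligned scans.

    Each scan is a ``(scan_id, volume, mask)`` triple; two scans model a
    test–retest pair acquired minutes apart.
    """

    case_id: str
    scans: list[tuple[str, ImageVolume, ROIMask]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.scans) <= 2:
            raise ValueError(f"a case must have 1 or 2 scans, got {len(self.scans)}")
        ids = [s[0] for s in self.scans]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate scan_id within case {self.case_id!r}")
        for scan_id, vol, mask in self.scans:
            if vol.shape != mask.shape:
                raise AlignmentError(
                    f"case {self.case_id!r} scan {scan_id!r}: mask shape "
                    f"{mask.shape} != volume shape {vol.shape}"
                )

    @property
    def scan_ids(self) -> list[str]:
        return [s[0] for s in self.scans]


@dataclass
class Cohort:
    """A list of cases, all with the same number of scans."""

    cases: list[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate case_id in cohort")
        n_scans = {len(c.scans) for c in self.cases}
        if len(n_scans) > 1:
            raise ManifestError(
                f"all cases must have the same number of scans, got {sorted(n_scans)}"
            )

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    @property
    def scan_ids(self) -> list[str]:
        return self.cases[0].scan_ids if self.cases else []


# ---------------------------------------------------------------------------
# volume / mask I/O


_NIFTI_HEADER_BYTES = 348


def _payload_bytes(p: Path) -> int:
    """Readable byte count of a NIfTI file, fully decompressing .gz payloads."""
    if p.name.endswith(".gz"):
        import gzip

        total = 0
        with gzip.open(p, "rb") as fh:
            while chunk := fh.read(1 << 20):
                total += len(chunk)
        return total
    return p.stat().st_size


def _reject_truncated_nifti(p: Path, img: sitk.Image) -> None:
    """NIfTI readers silently zero-fill short payloads; reject them instead."""
    if not (p.name.endswith(".nii") or p.name.endswith(".nii.gz")):
        return  # other formats fail loudly on their own
    expected = int(np.prod(img.GetSize())) * _bytes_per_voxel(img)
    try:
        available = _payload_bytes(p)
    except (OSError, EOFError) as exc:
        raise FormatError(f"truncated or corrupt file: {p}") from exc
    if available < expected + _NIFTI_HEADER_BYTES:
        raise FormatError(
            f"truncated volume file {p}: {available} bytes present, "
            f">= {expected + _NIFTI_HEADER_BYTES} required"
        )


def _bytes_per_voxel(img: sitk.Image) -> int:
    comp = max(1, img.GetNumberOfComponentsPerPixel())
    return comp * sitk.GetArrayViewFromImage(img).itemsize


def _read_sitk(path: str | Path) -> sitk.Image:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume file: {p}")
    try:
        img = sitk.ReadImage(str(p))
    except RuntimeError as exc:  # unreadable payload
        raise FormatError(f"cannot read {p}: {exc}") from exc
    _reject_truncated_nifti(p, img)
    return img


def _image_to_xyz(img: sitk.Image) -> tuple[np.ndarray, Triple, Triple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) or higher-dimensional
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D scalar volume, got {arr.ndim} dimensions")
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    return data, spacing, origin  # type: ignore[return-value]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI/NRRD scalar volume; intensities are returned unmodified."""
    data, spacing, origin = _image_to_xyz(_read_sitk(path))
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_mask(path: str | Path) -> ROIMask:
    """Read a mask volume; any nonzero voxel becomes foreground."""
    data, spacing, origin = _image_to_xyz(_read_sitk(path))
    return ROIMask(data=data, spacing=spacing, origin=origin)


def _to_sitk(data: np.ndarray, spacing: Triple, origin: Triple) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(origin))
    return img


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume.data, volume.spacing, volume.origin), str(p))
    return p


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    data = mask.data.astype(np.uint8)
    sitk.WriteImage(_to_sitk(data, mask.spacing, mask.origin), str(p))
    return p


# ---------------------------------------------------------------------------
# cohort manifests


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every volume/mask as ``.nii.gz`` plus a manifest CSV; return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cohort:
        for scan_id, vol, mask in case.scans:
            stem = f"{case.case_id}_{scan_id}"
            vpath = write_volume(vol, out / f"{stem}_volume.nii.gz")
            mpath = write_mask(mask, out / f"{stem}_mask.nii.gz")
            rows.append((case.case_id, scan_id, vpath.name, mpath.name))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        w.writerows(rows)
    return manifest


def load_cohort_manifest(path: str | Path) -> Cohort:
    """Load a cohort from a manifest CSV, shape-checking each volume/mask pair.

    Relative paths in the manifest are resolved against the manifest's
    own directory.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such manifest: {p}")
    with open(p, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames[:4]) != MANIFEST_COLUMNS:
            raise ManifestError(
                f"manifest header must be {','.join(MANIFEST_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        rows = list(reader)
    if not rows:
        raise ManifestError("empty manifest: at least 2 cases are required downstream")

    seen: set[tuple[str, str]] = set()
    by_case: dict[str, list[tuple[str, ImageVolume, ROIMask]]] = {}
    for row in rows:
        key = (row["case_id"], row["scan_id"])
        if key in seen:
            raise ManifestError(f"duplicate (case_id, scan_id) entry: {key}")
        seen.add(key)
        vol = read_volume(_resolve(p, row["volume_path"]))
        mask = read_mask(_resolve(p, row["mask_path"]))
        if vol.shape != mask.shape:
            raise AlignmentError(
                f"case {row['case_id']!r} scan {row['scan_id']!r}: mask shape "
                f"{mask.shape} does not match volume shape {vol.shape}"
            )
        by_case.setdefault(row["case_id"], []).append((row["scan_id"], vol, mask))
    cases = [CaseRecord(case_id=cid, scans=scans) for cid, scans in by_case.items()]
    return Cohort(cases=cases)


def _resolve(manifest_path: Path, entry: str) -> Path:
    q = Path(entry)
    return q if q.is_absolute() else manifest_path.parent / q


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: "FeatureTable", path: str | Path) -> Path:
    """Write a feature table to CSV at 17 significant digits (lossless for float64)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    frame = table.frame
    if frame.empty:
        raise ValueError("refusing to write an empty feature table")
    frame.to_csv(p, float_format="%.17g", na_rep="")
    return p


def read_feature_table(
    path: str | Path, arm_id: str = "", dialect: str = "", spec=None
) -> "FeatureTable":
    """Read a feature-table CSV (own output or an external toolkit's export).

    The CSV must carry ``case_id`` and ``scan_id`` columns plus the 43
    canonical feature columns; extra columns are ignored. Empty cells
    become NaN.
    """
    from .features import FEATURE_NAMES, FeatureTable
    import pandas as pd

    frame = pd.read_csv(path, index_col=["case_id", "scan_id"])
    missing = [n for n in FEATURE_NAMES if n not in frame.columns]
    if missing:
        raise ManifestError(
            f"feature table {path} is missing {len(missing)} canonical "
            f"feature columns, e.g. {missing[:3]}"
        )
    frame = frame[list(FEATURE_NAMES)].astype(float)
    frame.index = frame.index.set_levels(
        [frame.index.levels[0].astype(str), frame.index.levels[1].astype(str)]
    )
    return FeatureTable(frame=frame, arm_id=arm_id, dialect=dialect, spec=spec)
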