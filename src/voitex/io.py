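"""Cohort I/O: CT volumes, VOI masks, manifests and feature tables.

Volumes are held as 3-D arrays in Hounsfield units (HU) with the axial
(slice) axis last after canonical reorientation.  Masks are boolean grids on
the same voxel lattice.  The cohort manifest is a CSV with one row per
patient carrying the differentiation-grade group label.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: group label -> (tissue site, differentiation grade)
GROUP_DEFINITIONS: dict[str, tuple[str, str]] = {
    "BM": ("bone", "moderate"),
    "SW": ("soft", "well"),
    "SM": ("soft", "moderate"),
    "SP": ("soft", "poor"),
}

GROUP_ORDER: tuple[str, ...] = ("BM", "SW", "SM", "SP")


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT intensity grid in Hounsfield units.

    ``voxels`` is indexed (x, y, z) with z the axial slice axis; ``spacing``
    is the voxel size (dx, dy, dz) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {v.ndim}-D")
        if min(v.shape) < 1:
            raise ValueError(f"degenerate volume shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite intensities")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class VOIMask:
    """Binary volume-of-interest mask on the same grid as its CTVolume."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.voxels) != 0
        if m.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {m.ndim}-D")
        if not m.any():
            raise ValueError("VOI has no voxels")
        object.__setattr__(self, "voxels", m)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    group: str
    age: float
    sex: str
    tissue: str
    grade: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_DEFINITIONS:
            raise ValueError(f"unknown group label {self.group!r} for patient {self.patient_id}")
        tissue, grade = GROUP_DEFINITIONS[self.group]
        if (self.tissue, self.grade) != (tissue, grade):
            raise ValueError(
                f"patient {self.patient_id}: group {self.group} implies "
                f"(tissue={tissue}, grade={grade}), got (tissue={self.tissue}, grade={self.grade})"
            )
        if not self.age > 0:
            raise ValueError(f"patient {self.patient_id}: age must be positive, got {self.age}")


def read_nifti_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI volume; intensities are taken as HU (scl_* applied by nibabel)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got {len(img.shape)}-D: {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxel intensities in {path}")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(voxels=data, spacing=tuple(float(z) for z in zooms), orientation="RAS")


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read a single-series directory of single-frame CT slices into HU.

    Slices are sorted by position along the slice axis; stored values are
    mapped to HU via RescaleSlope*v + RescaleIntercept (required tags).
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"DICOM directory not found: {directory}")
    datasets = []
    for fn in sorted(directory.iterdir()):
        if fn.is_file():
            try:
                datasets.append(pydicom.dcmread(str(fn)))
            except Exception as exc:  # non-DICOM file in the directory
                raise ValueError(f"unreadable DICOM file {fn}: {exc}") from exc
    if not datasets:
        raise ValueError(f"no DICOM files in {directory}")

    uids = sorted({ds.SeriesInstanceUID for ds in datasets})
    if len(uids) > 1:
        raise ValueError(f"multiple series in {directory}: {', '.join(uids)}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in {directory}: {sorted(shapes)}")

    def slice_position(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=slice_position)

    hu_slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(
                f"missing RescaleSlope/RescaleIntercept in series {uids[0]}; "
                "cannot map stored values to HU"
            )
        arr = ds.pixel_array.astype(float)
        hu_slices.append(float(ds.RescaleSlope) * arr + float(ds.RescaleIntercept))

    # (rows, cols, slices) with the slice axis last
    voxels = np.stack(hu_slices, axis=-1)

    ds0 = datasets[0]
    row_sp, col_sp = (float(x) for x in ds0.PixelSpacing)
    if len(datasets) > 1 and all(hasattr(d, "ImagePositionPatient") for d in datasets):
        positions = [slice_position(d) for d in datasets]
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            dz = abs(dz) if dz != 0 else float(ds0.SliceThickness)
    else:
        dz = float(ds0.SliceThickness)
        logger.warning(
            "series %s: inter-slice distance unavailable, falling back to SliceThickness=%g",
            uids[0], dz,
        )
    return CTVolume(voxels=voxels, spacing=(row_sp, col_sp, dz), orientation="LPS")


def read_mask(path: str | os.PathLike, vol: CTVolume) -> VOIMask:
    """Read a NIfTI mask aligned to ``vol``; any nonzero voxel is foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D mask, got {len(img.shape)}-D: {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata())
    if data.shape != vol.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {vol.shape} ({path})"
        )
    if not (data != 0).any():
        raise ValueError(f"VOI has no voxels: {path}")
    return VOIMask(voxels=data != 0)


MANIFEST_COLUMNS = ("patient_id", "group", "age", "sex", "tissue", "grade")


def load_manifest(path: str | os.PathLike) -> list[CohortRecord]:
    """Load and validate a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"patient_id": str}, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                CohortRecord(
                    patient_id=str(row["patient_id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    tissue=str(row["tissue"]),
                    grade=str(row["grade"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"manifest {path}, row {i + 2}: {exc}") from exc
    return records


def manifest_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(MANIFEST_COLUMNS))


def summarize_manifest(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Group counts and percentages (one decimal), in canonical group order."""
    df = manifest_to_frame(records)
    n = len(df)
    rows = []
    for g in GROUP_ORDER:
        cnt = int((df["group"] == g).sum())
        rows.append({"group": g, "n": cnt, "percent": round(100.0 * cnt / n, 1) if n else 0.0})
    return pd.DataFrame(rows)


def _feature_sort_key(col: str) -> tuple[str, int]:
    # columns look like "<parameter>_q<d>"
    name, _, dist = col.rpartition("_q")
    if name and dist.isdigit():
        return (name, int(dist))
    return (col, 0)


def write_feature_table(
    rows: Sequence[Mapping[str, object]],
    path: str | os.PathLike,
    header_comment: str | None = None,
) -> Path:
    """Write per-patient feature rows to CSV with a deterministic column order.

    Each row is a mapping with ``patient_id``, ``group`` and identical sets of
    feature keys.  Columns: patient_id, group, then features sorted by
    parameter name then distance.  Floats are written with full precision so
    the decimal round-trip is exact.
    """
    if not rows:
        raise ValueError("no rows to write")
    feature_sets = [frozenset(k for k in r if k not in ("patient_id", "group")) for r in rows]
    if len(set(feature_sets)) != 1:
        raise ValueError("ragged rows: feature-name sets differ across patients")
    features = sorted(feature_sets[0], key=_feature_sort_key)
    cols = ["patient_id", "group", *features]
    df = pd.DataFrame([{c: r[c] for c in cols} for r in rows], columns=cols)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, comment="#",
                     float_precision="round_trip")
    if "patient_id" not in df.columns:
        raise ValueError(f"feature table {path} has no patient_id column")
    return df


def write_nifti(path: str | os.PathLike, voxels: np.ndarray, spacing: Iterable[float]) -> Path:
    """Write a 3-D array as NIfTI with the given voxel spacing (mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*list(spacing), 1.0])
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))
    return path
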