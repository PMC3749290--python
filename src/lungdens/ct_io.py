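"""Volumetric CT input/output and HU calibration checks.

The in-memory data model is deliberately small: a :class:`CTVolume` holds a
3D array of Hounsfield units in ``(slice, row, column)`` axis order together
with the voxel spacing in millimetres, and a :class:`LabelVolume` holds
integer masks on the same grid.  NIfTI and MetaImage files are read and
written through SimpleITK; DICOM series are read (read-only) through pydicom
so that missing rescale metadata and inconsistent slice geometry surface as
explicit errors.

All densitometry downstream is orientation-invariant, so direction cosines
are carried through round-trips but never interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
import SimpleITK as sitk

from .errors import (
    CalibrationMetadataError,
    DegenerateInputError,
    GeometryError,
    VolumeFormatError,
)

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

#: Default tolerance (HU) for the extracorporal-air calibration check.
DEFAULT_CALIBRATION_TOLERANCE_HU = 6.0

#: Default fraction of the lowest (posterior) rows per slice excluded from the
#: extracorporal-air region as the patient-table zone.
DEFAULT_TABLE_ROW_FRACTION = 0.15


def _as_tuple3(x: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class CTVolume:
    """A chest CT volume in Hounsfield units.

    Parameters
    ----------
    values:
        3D float array, axis order ``(slice, row, column)``.
    spacing:
        Voxel edge lengths in mm, same axis order as ``values``.
    origin:
        Physical coordinate of voxel (0, 0, 0) in mm.
    direction:
        Row-major 3x3 direction cosines in SimpleITK's (x, y, z) convention;
        preserved on round-trip, ignored by all computation.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (= cm^3)."""
        return math.prod(self.spacing) / 1000.0


@dataclass
class LabelVolume:
    """An integer-label mask on the same grid as its paired :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            arr = np.asarray(self.labels)
            if not np.all(arr == np.round(arr)):
                raise ValueError("labels must be integers")
            self.labels = arr.astype(np.int32)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return math.prod(self.spacing) / 1000.0


def check_same_grid(a: CTVolume | LabelVolume, b: CTVolume | LabelVolume) -> None:
    """Raise :class:`GeometryError` unless the two images share shape and spacing."""
    if a.shape != b.shape:
        raise GeometryError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=0, atol=1e-6):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


@dataclass
class CalibrationReport:
    """Result of the extracorporal-air attenuation check.

    Air outside the patient should reconstruct at -1000 HU; a systematic
    offset indicates a scanner calibration problem that would bias every
    density-mask metric.
    """

    extracorporal_air_mean: float
    extracorporal_air_sd: float
    tolerance: float
    n_voxels: int = 0

    @property
    def passed(self) -> bool:
        return abs(self.extracorporal_air_mean - (-1000.0)) <= self.tolerance


# ---------------------------------------------------------------------------
# File formats


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise VolumeFormatError(f"cannot infer image format from {path}")


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, column)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin, tuple(img.GetDirection())


def _to_sitk(
    arr: np.ndarray,
    spacing: Sequence[float],
    origin: Sequence[float],
    direction: Sequence[float],
) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(reversed(tuple(spacing))))
    img.SetOrigin(tuple(reversed(tuple(origin))))
    if len(direction) == 9:
        img.SetDirection(tuple(direction))
    return img


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no readable DICOM slices in {path}")

    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    first = slices[0]
    shape2d = (int(first.Rows), int(first.Columns))
    px = [float(v) for v in first.PixelSpacing]
    planes = []
    for ds in slices:
        if (int(ds.Rows), int(ds.Columns)) != shape2d:
            raise GeometryError("DICOM slices have inconsistent in-plane shape")
        if not np.allclose([float(v) for v in ds.PixelSpacing], px, atol=1e-6):
            raise GeometryError("DICOM slices have inconsistent pixel spacing")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise CalibrationMetadataError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; cannot convert to HU"
            )
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        planes.append(hu)
    if len(slices) > 1:
        zs = np.array([z_of(ds) for ds in slices])
        dz = np.diff(zs)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
            raise GeometryError("DICOM slice positions are not uniformly spaced")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))
    values = np.stack(planes, axis=0)
    origin = (0.0, 0.0, 0.0)
    if hasattr(first, "ImagePositionPatient"):
        x0, y0, z0 = (float(v) for v in first.ImagePositionPatient)
        origin = (z0, y0, x0)
    return CTVolume(values, (slice_spacing, px[0], px[1]), origin)


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume in HU from NIfTI, MetaImage, or a DICOM series directory.

    DICOM rescale slope/intercept is applied so stored values are HU; its
    absence raises :class:`CalibrationMetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such path: {path}")
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    if fmt not in ("nifti", "metaimage"):
        raise VolumeFormatError(f"unknown format {fmt!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message depends on ITK
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    arr, spacing, origin, direction = _from_sitk(img)
    return CTVolume(arr.astype(np.float64), spacing, origin, direction)


def read_label_volume(path: str | Path, format: str | None = None) -> LabelVolume:
    """Read an integer label mask from NIfTI or MetaImage."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such path: {path}")
    fmt = format or _infer_format(path)
    if fmt not in ("nifti", "metaimage"):
        raise VolumeFormatError(f"unsupported label format {fmt!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    arr, spacing, origin, direction = _from_sitk(img)
    return LabelVolume(np.rint(arr).astype(np.int32), spacing, origin, direction)


def write_volume(
    volume: CTVolume | LabelVolume, path: str | Path, format: str | None = None
) -> None:
    """Write a volume losslessly: HU as int16, labels as uint8/uint16."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("nifti", "metaimage"):
        raise VolumeFormatError(f"unsupported output format {fmt!r}")
    if isinstance(volume, LabelVolume):
        maxlab = int(volume.labels.max(initial=0))
        dtype = np.uint8 if maxlab < 256 else np.uint16
        arr = volume.labels.astype(dtype)
    else:
        arr = np.rint(np.clip(volume.values, -32768, 32767)).astype(np.int16)
    img = _to_sitk(arr, volume.spacing, volume.origin, volume.direction)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Calibration


def check_air_calibration(
    volume: CTVolume,
    body_mask: LabelVolume,
    tolerance: float = DEFAULT_CALIBRATION_TOLERANCE_HU,
    table_row_fraction: float = DEFAULT_TABLE_ROW_FRACTION,
) -> CalibrationReport:
    """Check the mean HU of air outside the body against -1000 HU.

    The extracorporal region is every non-body voxel outside the patient-table
    zone, taken as the lowest ``table_row_fraction`` of rows in each slice
    (the table sits posterior to a supine patient, i.e. at high row indices).
    """
    check_same_grid(volume, body_mask)
    ny = volume.shape[1]
    n_table = int(round(table_row_fraction * ny))
    region = body_mask.labels == 0
    if n_table > 0:
        region = region.copy()
        region[:, ny - n_table :, :] = False
    vals = volume.values[region]
    if vals.size == 0:
        raise DegenerateInputError("empty extracorporal air region")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return CalibrationReport(mean, sd, float(tolerance), int(vals.size))
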