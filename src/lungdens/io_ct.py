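"""Reading and writing CT volumes and lung masks.

Internal axis convention
------------------------
All in-memory arrays are indexed ``(x, y, z)`` with ``z`` the cranio-caudal
axis (index increasing toward the head) and ``y`` the ventro-dorsal axis.
Files are reoriented to this convention at read time regardless of their
on-disk order, so downstream code never has to reason about orientation.

Hounsfield calibration
----------------------
NIfTI voxel values are trusted as Hounsfield units (after the header's
``scl_slope``/``scl_inter``, which nibabel applies).  DICOM stored values are
always rescaled with the series' RescaleSlope/RescaleIntercept, so a stored
value of 24 with slope 1 and intercept -1024 reads back as -1000 HU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

log = logging.getLogger(__name__)

#: tolerated relative deviation of individual DICOM slice gaps from the median
SLICE_GAP_TOLERANCE = 0.10


class LungDensError(Exception):
    """Base class for errors raised by this package."""


class CalibrationError(LungDensError):
    """Missing or contradictory HU-calibration / spacing metadata."""


class SeriesAmbiguityError(LungDensError):
    """A DICOM directory holds more than one series."""


class GeometryError(LungDensError):
    """Inconsistent geometry (non-uniform slice gaps, dimension mismatch)."""


class ParameterError(LungDensError):
    """An argument is outside its documented domain."""


@dataclass
class CTVolume:
    """A Hounsfield-calibrated CT volume on a regular anisotropic grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values.  Natively integral on real scanners; float arrays are
        accepted and used as given.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, all strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    axis_order : str
        Tag documenting the in-memory convention; always ``"xyz"`` here.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or 0 in self.voxels.shape:
            raise GeometryError("voxel grid must be 3-D and non-empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise CalibrationError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class MaskVolume:
    """Boolean grid aligned voxel-for-voxel with a :class:`CTVolume`."""

    flags: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3 or 0 in self.flags.shape:
            raise GeometryError("mask grid must be 3-D and non-empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    def check_aligned(self, vol: CTVolume) -> None:
        if self.shape != vol.shape:
            raise GeometryError(f"mask shape {self.shape} != volume shape {vol.shape}")


def apply_hu_calibration(raw, slope: float, intercept: float) -> np.ndarray:
    """Affine HU calibration ``raw * slope + intercept`` (elementwise)."""
    if slope == 0:
        raise ParameterError("rescale slope must be non-zero")
    return np.asarray(raw, dtype=np.float64) * slope + intercept


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: Path):
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # enforce RAS -> (x, y, z)
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise CalibrationError(f"{path}: missing or non-positive voxel spacing")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = img.get_fdata(dtype=np.float32)
    return data, tuple(float(z) for z in zooms), origin


def read_nifti_volume(path) -> CTVolume:
    data, spacing, origin = _load_nifti(Path(path))
    return CTVolume(data, spacing, origin)


def read_mask(path) -> MaskVolume:
    data, spacing, origin = _load_nifti(Path(path))
    return MaskVolume(data > 0.5, spacing, origin)


def write_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI-1; round-trips voxels and spacing exactly."""
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def write_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(mask.flags.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM files are simply skipped
            log.debug("skipping non-DICOM file %s", f)
    if not datasets:
        raise LungDensError(f"{path}: no readable DICOM slices")

    series = {ds.get("SeriesInstanceUID", "") for ds in datasets}
    if len(series) > 1:
        raise SeriesAmbiguityError(
            f"{path}: directory holds {len(series)} series; expected exactly one")

    def z_of(ds):
        ipp = ds.get("ImagePositionPatient")
        if ipp is None:
            raise CalibrationError(f"{path}: slice without ImagePositionPatient")
        return float(ipp[2])

    datasets.sort(key=z_of)

    first = datasets[0]
    ps = first.get("PixelSpacing")
    if ps is None:
        raise CalibrationError(f"{path}: PixelSpacing missing")
    dy, dx = float(ps[0]), float(ps[1])  # DICOM stores (row, col) spacing

    if len(datasets) > 1:
        zs = np.array([z_of(ds) for ds in datasets])
        gaps = np.diff(zs)
        dz = float(np.median(gaps))
        if dz <= 0:
            raise GeometryError(f"{path}: duplicate or unordered slice positions")
        if np.any(np.abs(gaps - dz) > SLICE_GAP_TOLERANCE * dz):
            raise GeometryError(
                f"{path}: non-uniform slice gaps beyond {SLICE_GAP_TOLERANCE:.0%} tolerance")
    else:
        dz = float(first.get("SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        hu = apply_hu_calibration(ds.pixel_array, slope, intercept)
        # pixel_array is (rows, cols) = (y, x); transpose to (x, y)
        slices.append(hu.T)
    voxels = np.stack(slices, axis=2).astype(np.float32)

    ipp = first.get("ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return CTVolume(voxels, (dx, dy, dz), origin)


def read_ct_volume(path, format_hint: str = "auto") -> CTVolume:
    """Read a CT volume from NIfTI or a single-series DICOM directory.

    ``format_hint`` is one of ``{"nifti", "dicom_dir", "auto"}``; ``auto``
    dispatches on whether *path* is a directory.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if format_hint == "auto":
        format_hint = "dicom_dir" if p.is_dir() else "nifti"
    if format_hint == "nifti":
        return read_nifti_volume(p)
    if format_hint == "dicom_dir":
        return _read_dicom_dir(p)
    raise ParameterError(f"unknown format hint {format_hint!r}")
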