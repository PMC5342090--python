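"""Image/mask containers, NIfTI & DICOM-series I/O, ROI cropping and mask geometry.

Conventions
-----------
Arrays are indexed ``values[i, j, k]`` with ``k`` the slice (z) axis and
``spacing_mm = (dx, dy, dz)`` matching the three axes. Voxel indices are
0-based; image and mask always share one grid. Masks are inputs — there is
no contour rasterization here.

Surface area is measured by exact voxel-face counting: every face between an
in-mask voxel and an out-of-mask (or out-of-grid) voxel contributes the area
of that face. This is deterministic and exact on the voxel grid, but it is a
different estimator from marching-cubes mesh areas and systematically larger
for smooth shapes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ROIMask",
    "GeometrySet",
    "MaskedRegion",
    "read_volume",
    "read_mask",
    "write_nifti",
    "crop_with_mask",
    "compute_geometry",
]


class FormatError(ValueError):
    """Raised when an on-disk image violates the expected geometry/metadata."""


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU or filter response) with per-axis spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: private per-volume annotations (e.g. the phantom generator's continuous
    #: fields); never serialized, never compared.
    aux: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz


@dataclass
class ROIMask:
    """A binary 3D grid aligned to an :class:`ImageVolume`."""

    flags: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.flags.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class GeometrySet:
    """Mask geometry: physical volume, voxel-face surface area and their ratio."""

    volume_mm3: float
    area_mm2: float
    v_over_a_mm: float


@dataclass
class MaskedRegion:
    """An image cropped to the mask's bounding box, with out-of-mask voxels
    excluded via NaN sentinels so background can never leak into statistics."""

    values: np.ndarray  # NaN outside the mask
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    bbox: tuple[slice, slice, slice]

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# I/O


def _nifti_spacing(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"non-positive or missing voxel spacing in header: {zooms}")
    return tuple(float(z) for z in zooms)


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    return ImageVolume(values=data, spacing_mm=_nifti_spacing(img))


def _read_dicom_series(directory: Path) -> ImageVolume:
    import pydicom

    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.suffix == ""
    )
    datasets = []
    for p in files:
        if p.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM slices in {directory}")

    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    first = datasets[0]
    pixel_spacing = [float(v) for v in first.PixelSpacing]  # (row, col) = (dy, dx)
    for ds in datasets:
        if [float(v) for v in ds.PixelSpacing] != pixel_spacing:
            raise FormatError("inconsistent PixelSpacing across the series")
        if ds.pixel_array.shape != first.pixel_array.shape:
            raise FormatError("inconsistent slice matrix across the series")

    if len(datasets) > 1:
        zs = np.array([z_of(ds) for ds in datasets])
        steps = np.diff(zs)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-3):
            raise FormatError("slice positions are not uniformly spaced")
        dz = float(steps[0])
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise FormatError("single-slice series without SliceThickness")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (rows, cols) = (y, x); transpose to our (x, y) order
        slices.append((arr * slope + intercept).T)
    values = np.stack(slices, axis=2)
    return ImageVolume(values=values, spacing_mm=(pixel_spacing[1], pixel_spacing[0], dz))


def read_volume(path: str | os.PathLike, format: str | None = None) -> ImageVolume:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"``, ``"dicom_series"`` or ``None`` to auto-detect
    (directories are treated as DICOM series). DICOM HU rescale slope and
    intercept are applied; spacing is taken from the headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def read_mask(path: str | os.PathLike) -> ROIMask:
    """Read a binary ROI mask from a NIfTI volume (nonzero = in-mask)."""
    vol = read_volume(path, format="nifti")
    return ROIMask(flags=vol.values > 0.5, spacing_mm=vol.spacing_mm)


def write_nifti(obj: ImageVolume | ROIMask, path: str | os.PathLike) -> None:
    """Write an image or mask as NIfTI with spacing encoded in the affine."""
    if isinstance(obj, ROIMask):
        data = obj.flags.astype(np.uint8)
    else:
        data = obj.values
    affine = np.diag(list(obj.spacing_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# ROI cropping and geometry


def crop_with_mask(image: ImageVolume, mask: ROIMask) -> MaskedRegion:
    """Crop ``image`` to the mask bounding box; out-of-mask voxels become NaN.

    In-mask values are passed through unchanged, so any in-mask statistic of
    the crop equals that of the original.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    idx = np.nonzero(mask.flags)
    bbox = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    sub_mask = mask.flags[bbox]
    sub_vals = image.values[bbox].copy()
    sub_vals[~sub_mask] = np.nan
    return MaskedRegion(values=sub_vals, mask=sub_mask, spacing_mm=image.spacing_mm, bbox=bbox)


def compute_geometry(mask: ROIMask) -> GeometrySet:
    """Volume, voxel-face surface area and V/A of a binary mask.

    volume = (in-mask voxel count) x dx*dy*dz. Area sums the areas of all
    faces that separate an in-mask voxel from an out-of-mask voxel or from
    the grid border.
    """
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask has no geometry")
    dx, dy, dz = mask.spacing_mm
    volume = n * dx * dy * dz

    face_area = (dy * dz, dx * dz, dx * dy)
    m = mask.flags
    area = 0.0
    for axis, fa in enumerate(face_area):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        transitions = np.diff(padded.astype(np.int8), axis=axis) != 0
        area += fa * int(transitions.sum())
    return GeometrySet(volume_mm3=volume, area_mm2=area, v_over_a_mm=volume / area)
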