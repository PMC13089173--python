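"""Voxel volumes, structure masks and image I/O.

Coordinate convention used throughout the package: a fixed patient frame
with x = patient-left, y = patient-posterior, z = patient-superior (the
DICOM patient coordinate system for a supine patient).  Array index
``(i, j, k)`` maps to the physical position ``origin_mm + index *
spacing_mm`` — i.e. ``origin_mm`` is the *center* of voxel ``(0, 0, 0)``
and all geometry is done in physical millimetres on voxel centers.

Only axis-aligned volumes are supported; obliquely acquired images are
rejected rather than silently resampled.
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "StructureMask",
    "grids_match",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "average_intensity_projection",
    "expand_margin",
    "union_masks",
    "itv_from_gtvs",
]

#: structure roles with a target (tumour) semantic
TARGET_ROLES = frozenset({"GTV", "CTV", "ITV"})


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return v


@dataclass
class VoxelVolume:
    """A 3D scalar grid (HU or RSP) in the patient frame.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values.
    spacing_mm : ndarray, shape (3,)
        Strictly positive per-axis voxel size.
    origin_mm : ndarray, shape (3,)
        Physical position of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_center(self, index) -> np.ndarray:
        """Physical position (mm) of a voxel center."""
        return self.origin_mm + np.asarray(index, dtype=float) * self.spacing_mm

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.spacing_mm.copy(), self.origin_mm.copy())


@dataclass
class StructureMask:
    """A binary labelmap on the same grid as its parent volume."""

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    role: str = "GTV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.role in TARGET_ROLES and not self.data.any():
            raise ValueError(f"target mask with role {self.role!r} is empty")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing_mm))

    def copy(self) -> "StructureMask":
        return replace(self, data=self.data.copy())


def grids_match(a, b, atol: float = 1e-6) -> bool:
    """Whether two volumes/masks live on the same voxel grid."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing_mm, b.spacing_mm, atol=atol)
        and np.allclose(a.origin_mm, b.origin_mm, atol=atol)
    )


def _require_same_grid(items, what: str) -> None:
    first = items[0]
    for k, item in enumerate(items[1:], start=1):
        if not grids_match(first, item):
            raise ValueError(
                f"{what}: grid mismatch between item 0 "
                f"(shape {first.shape}, spacing {first.spacing_mm}) and item {k} "
                f"(shape {item.shape}, spacing {item.spacing_mm})"
            )


# ---------------------------------------------------------------------------
# NIfTI read / write
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def _geometry_from_affine(affine: np.ndarray, path) -> tuple:
    M = affine[:3, :3]
    off_diag = M - np.diag(np.diag(M))
    if np.max(np.abs(off_diag)) > 1e-3 or np.any(np.diag(M) <= 0):
        raise ValueError(
            f"{path}: non-axis-aligned (or axis-flipped) orientation is unsupported; "
            "resample the image to an axis-aligned grid first"
        )
    return np.diag(M).copy(), affine[:3, 3].copy()


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI file or a DICOM CT series directory into a :class:`VoxelVolume`."""
    path = os.fspath(path)
    if os.path.isdir(path):
        return read_dicom_series(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the filename
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    spacing, origin = _geometry_from_affine(img.affine, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VoxelVolume(data, spacing, origin)


def write_volume(vol: VoxelVolume, path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz); float64 so round trips are exact."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine_from_geometry(vol.spacing_mm, vol.origin_mm))
    img.header.set_data_dtype(np.float64)
    nib.save(img, os.fspath(path))


def read_mask(path, role: str = "GTV") -> StructureMask:
    vol = read_volume(path)
    return StructureMask(vol.data > 0.5, vol.spacing_mm, vol.origin_mm, role=role)


def write_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_from_geometry(mask.spacing_mm, mask.origin_mm)
    )
    img.header.set_data_dtype(np.uint8)
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# DICOM CT series (read-only)
# ---------------------------------------------------------------------------

def read_dicom_series(dirpath) -> VoxelVolume:
    """Read an axis-aligned DICOM CT series (one file per slice) as HU.

    Slices are sorted by their superior-inferior position; an uneven slice
    gap (missing slice) is an error naming the gap location.
    """
    import pydicom

    dirpath = os.fspath(dirpath)
    slices = []
    for fname in sorted(glob.glob(os.path.join(dirpath, "*"))):
        if os.path.isdir(fname):
            continue
        try:
            ds = pydicom.dcmread(fname)
        except Exception:  # noqa: BLE001 - skip non-DICOM clutter
            continue
        if not hasattr(ds, "PixelData") or not hasattr(ds, "ImagePositionPatient"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM image slices found in {dirpath}")

    iop = np.asarray(getattr(slices[0], "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise ValueError(f"{dirpath}: non-axis-aligned DICOM orientation {iop} is unsupported")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError(f"{dirpath}: duplicate slice positions at z = {zs[np.argmin(dz)]:.3f} mm")
        if (dz.max() - dz.min()) > 0.01 * np.median(dz):
            i = int(np.argmax(dz))
            raise ValueError(
                f"{dirpath}: inconsistent slice spacing — gap of {dz[i]:.3f} mm between "
                f"z = {zs[i]:.3f} and z = {zs[i + 1]:.3f} mm (expected {np.median(dz):.3f} mm)"
            )
        z_spacing = float(np.median(dz))
    else:
        z_spacing = float(getattr(slices[0], "SliceThickness", 1.0))

    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)  # (row=y, col=x)
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    # slice arrays are [row=y, col=x]; volume is [x, y, z]
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return VoxelVolume(data, np.array([col_sp, row_sp, z_spacing]), origin)


# ---------------------------------------------------------------------------
# Derived volumes and mask algebra
# ---------------------------------------------------------------------------

def average_intensity_projection(phases) -> VoxelVolume:
    """Voxelwise arithmetic mean of the breathing-phase volumes (the AIP-CT)."""
    phases = list(phases)
    if not phases:
        raise ValueError("average_intensity_projection needs at least one phase")
    _require_same_grid(phases, "average_intensity_projection")
    data = np.mean(np.stack([p.data for p in phases]), axis=0)
    return VoxelVolume(data, phases[0].spacing_mm.copy(), phases[0].origin_mm.copy())


def expand_margin(mask: StructureMask, margin_mm: float, role: str | None = None) -> StructureMask:
    """Isotropic margin expansion in physical millimetres.

    A voxel belongs to the output exactly when its center lies within
    ``margin_mm`` (Euclidean distance) of some input voxel center, which
    handles anisotropic spacing without structuring-element approximation.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    out_role = mask.role if role is None else role
    if margin_mm == 0 or not mask.data.any():
        return replace(mask, data=mask.data.copy(), role=out_role)

    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing_mm)
    data = dist <= margin_mm + 1e-9

    idx = np.argwhere(mask.data)
    lo = idx.min(axis=0) * mask.spacing_mm
    hi = idx.max(axis=0) * mask.spacing_mm
    extent = (np.array(mask.shape) - 1) * mask.spacing_mm
    if np.any(lo - margin_mm < -1e-9) or np.any(hi + margin_mm > extent + 1e-9):
        warnings.warn(
            f"margin expansion of {margin_mm} mm reaches past the image grid; "
            "the expanded mask is clipped at the grid boundary",
            stacklevel=2,
        )
    return StructureMask(data, mask.spacing_mm.copy(), mask.origin_mm.copy(), role=out_role)


def union_masks(masks, role: str | None = None) -> StructureMask:
    """Voxelwise logical OR of masks on a shared grid."""
    masks = list(masks)
    if not masks:
        raise ValueError("union_masks needs at least one mask")
    _require_same_grid(masks, "union_masks")
    data = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        data |= m.data
    out_role = masks[0].role if role is None else role
    return StructureMask(data, masks[0].spacing_mm.copy(), masks[0].origin_mm.copy(), role=out_role)


def itv_from_gtvs(gtv_masks, margin_mm: float = 5.0):
    """Build per-phase CTVs (GTV + isotropic margin) and their union, the ITV.

    Returns ``(ctvs, itv)``.
    """
    ctvs = [expand_margin(g, margin_mm, role="CTV") for g in gtv_masks]
    itv = union_masks(ctvs, role="ITV")
    return ctvs, itv
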