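"""Volumes, masks, NIfTI I/O, isotropic resampling and intensity normalisation.

Coordinate convention: ``data[i, j, k]`` with 0-based voxel indices, axis order
(x, y, z) so an axial slice is ``data[:, :, k]``; world coordinates are
``origin + index * spacing`` (axis-aligned RAS, no oblique affines).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DimensionError,
    FormatError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "Volume",
    "Mask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "zscore_normalize",
    "pad_crop",
    "mask_centroid",
]


def _check_grid(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise DimensionError(f"expected a 3D grid, got {data.ndim}D shape {data.shape}")
    if len(spacing) != 3 or len(origin) != 3:
        raise DimensionError("spacing and origin must have 3 components")
    if any(not (s > 0) for s in spacing):
        raise ValidationError(f"spacing must be strictly positive, got {tuple(spacing)}")


@dataclass(frozen=True)
class Volume:
    """3D intensity grid in Hounsfield units (or a normalized scale) with
    voxel spacing and origin in millimetres."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        _check_grid(data, self.spacing, self.origin)
        if not np.all(np.isfinite(data)):
            raise ValidationError("volume contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass(frozen=True)
class Mask:
    """Binary 3D grid aligned voxel-for-voxel with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        _check_grid(data, self.spacing, self.origin)
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "Mask":
        return replace(self, data=data)


def _load_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path) -> Volume:
    data, spacing, origin = _load_nifti(path)
    return Volume(data.astype(np.float64), spacing, origin)


def read_mask(path) -> Mask:
    data, spacing, origin = _load_nifti(path)
    return Mask(data, spacing, origin)


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def resample_isotropic(grid, target_mm: float = 1.0, mode: str | None = None):
    """Resample a Volume or Mask to isotropic ``target_mm`` spacing.

    Linear interpolation for volumes, nearest-neighbour for masks (which
    preserves the binary value set), unless ``mode`` overrides the default.
    """
    if not target_mm > 0:
        raise ParameterError(f"target_mm must be > 0, got {target_mm}")
    if mode is None:
        mode = "nearest" if isinstance(grid, Mask) else "linear"
    if mode not in ("linear", "nearest"):
        raise ParameterError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    order = 1 if mode == "linear" else 0
    factors = np.asarray(grid.spacing, dtype=float) / target_mm
    if np.allclose(factors, 1.0):
        return grid
    out = ndimage.zoom(
        grid.data.astype(np.float64),
        factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    spacing = (target_mm,) * 3
    if isinstance(grid, Mask):
        return Mask(np.rint(out).astype(np.uint8), spacing, grid.origin)
    return Volume(out, spacing, grid.origin)


def zscore_normalize(vol: Volume) -> Volume:
    """Subtract the mean intensity and divide by the standard deviation."""
    sd = float(vol.data.std())
    if sd == 0.0:
        raise DegenerateInputError("constant volume: standard deviation is zero")
    return vol.with_data((vol.data - vol.data.mean()) / sd)


def mask_centroid(mask: Mask) -> tuple:
    """Voxel-index centroid of a mask (float per axis)."""
    if mask.is_empty():
        raise DegenerateInputError("cannot take the centroid of an empty mask")
    idx = np.argwhere(mask.data)
    return tuple(float(c) for c in idx.mean(axis=0))


def pad_crop(grid, target_shape, center=None):
    """Pad (with zeros) and/or crop to exactly ``target_shape``.

    ``center`` is a voxel-index point (floats allowed; rounded down so even
    target sizes tie-break toward the lower index) or None for the geometric
    center. Crop windows are clamped so they stay in bounds; when the input is
    smaller than the target along an axis it is placed fully inside the
    padded output.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ParameterError(f"target_shape must be 3 positive ints, got {target_shape}")
    shape = grid.data.shape
    if center is None:
        center = tuple(s // 2 for s in shape)
    cidx = tuple(int(math.floor(c)) for c in center)

    out = np.zeros(target_shape, dtype=grid.data.dtype)
    in_slices, out_slices, shift = [], [], []
    for s, t, c in zip(shape, target_shape, cidx):
        if t <= s:
            start = min(max(c - t // 2, 0), s - t)
            in_slices.append(slice(start, start + t))
            out_slices.append(slice(0, t))
            shift.append(start)
        else:
            ostart = min(max(t // 2 - c, 0), t - s)
            in_slices.append(slice(0, s))
            out_slices.append(slice(ostart, ostart + s))
            shift.append(-ostart)
    out[tuple(out_slices)] = grid.data[tuple(in_slices)]
    origin = tuple(o + sh * sp for o, sh, sp in zip(grid.origin, shift, grid.spacing))
    if isinstance(grid, Mask):
        return Mask(out, grid.spacing, origin)
    return Volume(out, grid.spacing, origin)
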