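"""Volumes, masks, resampling and gray-level quantization.

Images are CT volumes in Hounsfield units on a regular voxel lattice with
anisotropic spacing.  Before any texture is measured, a case is resampled to
a normalized 1 x 1 x 5 mm voxel grid and the tumor ROI is quantized to a
fixed number of gray levels (64 by default) with equal-width bins spanning
the ROI's own intensity range; this makes every downstream feature invariant
to affine intensity rescaling and to the scanner's native grid.

Conventions: arrays are indexed (x, y, z) and 0-based, masks are {0, 1}
uint8, spacing is millimetres per voxel, and the NIfTI affine carries the
world transform on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, IncompatibleGridError, InvalidArgumentError

__all__ = [
    "ImageVolume",
    "RoiMask",
    "QuantizedRoi",
    "read_case",
    "write_case",
    "resample",
    "quantize_roi",
]

DEFAULT_SPACING = (1.0, 1.0, 5.0)
DEFAULT_N_LEVELS = 64


@dataclass
class ImageVolume:
    """A 3D intensity grid (HU) with voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise InvalidArgumentError("volume grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.grid)):
            raise InvalidArgumentError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class RoiMask:
    """Binary tumor mask on the same lattice as its companion volume."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = (np.asarray(self.grid) > 0).astype(np.uint8)
        if self.grid.ndim != 3:
            raise InvalidArgumentError("mask grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError(f"spacing must be positive, got {self.spacing}")
        if not self.grid.any():
            raise EmptyRoiError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class QuantizedRoi:
    """ROI voxels mapped to integer gray levels 1..n_levels.

    ``levels`` is a full 3D integer array, 0 outside the ROI; ``bin_edges``
    records the monotone intensity-to-level map actually applied.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    roi_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        inside = self.levels[self.mask > 0]
        if inside.size == 0:
            raise EmptyRoiError("quantized ROI is empty")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise InvalidArgumentError("levels outside 1..n_levels")
        if self.roi_values is None:
            self.roi_values = inside.astype(np.int64)

    @property
    def level_probabilities(self) -> np.ndarray:
        """p(i) for i = 1..n_levels: fraction of ROI voxels at each level."""
        counts = np.bincount(self.roi_values, minlength=self.n_levels + 1)[1:]
        return counts / counts.sum()


def _check_grid(vol: ImageVolume, mask: RoiMask) -> None:
    if vol.shape != mask.shape:
        raise IncompatibleGridError(
            f"volume shape {vol.shape} != mask shape {mask.shape}"
        )
    if not np.allclose(vol.spacing, mask.spacing):
        raise IncompatibleGridError(
            f"volume spacing {vol.spacing} != mask spacing {mask.spacing}"
        )


def read_case(volume_path, mask_path) -> tuple[ImageVolume, RoiMask]:
    """Load a (volume, mask) NIfTI pair and validate that grids agree."""
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vspacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    mspacing = tuple(float(z) for z in mimg.header.get_zooms()[:3])
    vol = ImageVolume(np.asarray(vimg.dataobj, dtype=np.float64), vspacing,
                      tuple(vimg.affine[:3, 3]))
    mdata = np.asarray(mimg.dataobj)
    if mdata.shape != vol.shape or not np.allclose(vspacing, mspacing):
        raise IncompatibleGridError(
            f"mask grid {mdata.shape}@{mspacing} incompatible with "
            f"volume {vol.shape}@{vspacing}"
        )
    if not (mdata > 0).any():
        raise EmptyRoiError(f"mask {mask_path} is empty")
    mask = RoiMask(mdata, mspacing, tuple(mimg.affine[:3, 3]))
    return vol, mask


def write_case(vol: ImageVolume, mask: RoiMask, volume_path, mask_path) -> None:
    """Write a case as NIfTI-1 with the spacing encoded in the affine."""
    _check_grid(vol, mask)
    nib.save(nib.Nifti1Image(vol.grid.astype(np.float64), vol.affine()),
             str(volume_path))
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine()),
             str(mask_path))


def resample(
    vol: ImageVolume,
    mask: RoiMask,
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[ImageVolume, RoiMask]:
    """Resample a case to ``target_spacing`` (linear image, nearest mask)."""
    _check_grid(vol, mask)
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise InvalidArgumentError(f"target spacing must be positive: {target}")
    if np.allclose(vol.spacing, target):
        return vol, mask
    zoom = np.array(vol.spacing) / np.array(target)
    new_grid = ndimage.zoom(vol.grid, zoom, order=1, mode="nearest",
                            grid_mode=True)
    new_mask = ndimage.zoom(mask.grid, zoom, order=0, mode="nearest",
                            grid_mode=True, output=np.uint8)
    # nearest-neighbour zoom can round shapes independently of the image path
    if new_mask.shape != new_grid.shape:
        pad = [(0, a - b) for a, b in zip(new_grid.shape, new_mask.shape)]
        new_mask = np.pad(new_mask, pad)[: new_grid.shape[0],
                                         : new_grid.shape[1],
                                         : new_grid.shape[2]]
    if not new_mask.any():
        raise EmptyRoiError("resampling removed every foreground voxel")
    return (
        ImageVolume(new_grid, target, vol.origin),
        RoiMask(new_mask, target, mask.origin),
    )


def quantize_roi(vol: ImageVolume, mask: RoiMask,
                 n_levels: int = DEFAULT_N_LEVELS) -> QuantizedRoi:
    """Equal-width min-max quantization of ROI intensities to 1..n_levels.

    level(v) = min(n, 1 + floor(n * (v - vmin) / (vmax - vmin))); a constant
    ROI maps every voxel to level 1 (the degenerate branch, not an error).
    """
    _check_grid(vol, mask)
    if n_levels < 2:
        raise InvalidArgumentError("n_levels must be >= 2")
    fg = mask.grid > 0
    values = vol.grid[fg]
    vmin, vmax = float(values.min()), float(values.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if vmax > vmin:
        lv = 1 + np.floor(n_levels * (values - vmin) / (vmax - vmin))
        levels[fg] = np.minimum(n_levels, lv).astype(np.int32)
        edges = vmin + (vmax - vmin) * np.arange(n_levels + 1) / n_levels
    else:
        levels[fg] = 1
        edges = np.array([vmin, vmax])
    return QuantizedRoi(levels, mask.grid.copy(), int(n_levels), edges,
                        spacing=vol.spacing)
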