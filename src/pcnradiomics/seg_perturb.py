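"""Random per-slice expansion/erosion of tumor masks.

Manual tumor delineation is uncertain at the boundary; to screen features
for robustness against that uncertainty, each axial slice of the mask is
independently expanded, eroded or kept unchanged (uniform choice) with a
disk structuring element whose radius is drawn uniformly from 1..4 pixels.
Morphology is strictly in-plane — slices are perturbed, never merged through
the z axis — and a slice fully erased by erosion keeps its centroid voxel so
the perturbed mask can never become empty.

The per-slice random draws come from counter-based substreams keyed by
(seed, case_id, variant_index, slice_index); a given slice's perturbation is
therefore reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import EmptyRoiError, InvalidArgumentError
from .volume_io import RoiMask

__all__ = ["PerturbationSpec", "perturb_mask", "make_segmentation_set"]


@dataclass(frozen=True)
class PerturbationSpec:
    min_px: int = 1
    max_px: int = 4
    seed: int = 0
    n_variants: int = 2

    def __post_init__(self):
        if not 1 <= self.min_px <= self.max_px:
            raise InvalidArgumentError("need 1 <= min_px <= max_px")
        if self.n_variants < 0:
            raise InvalidArgumentError("n_variants must be >= 0")


def _slice_action(rng: np.random.Generator, spec: PerturbationSpec) -> tuple[str, int]:
    """Draw (action, radius) for one slice.  Kept module-level so tests can
    stub the action stream."""
    action = ("keep", "expand", "erode")[int(rng.integers(3))]
    radius = int(rng.integers(spec.min_px, spec.max_px + 1))
    return action, radius


def _restore_core(original_slice: np.ndarray) -> np.ndarray:
    """Single-voxel core at the (rounded) centroid of the original slice."""
    out = np.zeros_like(original_slice)
    idx = np.argwhere(original_slice > 0)
    cx, cy = np.round(idx.mean(axis=0)).astype(int)
    out[cx, cy] = 1
    return out


def perturb_mask(
    mask: RoiMask,
    spec: PerturbationSpec,
    variant_index: int,
    case_id: str = "",
) -> RoiMask:
    """One alternative segmentation: per-slice expand/erode/keep."""
    from .rng import substream

    grid = mask.grid
    if not grid.any():
        raise EmptyRoiError("cannot perturb an empty mask")
    out = np.zeros_like(grid)
    for z in range(grid.shape[2]):
        sl = grid[:, :, z]
        if not sl.any():
            continue
        rng = substream(spec.seed, case_id, int(variant_index), z)
        action, radius = _slice_action(rng, spec)
        if action == "keep":
            new = sl.copy()
        elif action == "expand":
            new = ndimage.binary_dilation(sl, structure=disk(radius)).astype(np.uint8)
        else:
            new = ndimage.binary_erosion(sl, structure=disk(radius)).astype(np.uint8)
            if not new.any():
                new = _restore_core(sl)
        out[:, :, z] = new
    return RoiMask(out, mask.spacing, mask.origin)


def make_segmentation_set(
    mask: RoiMask, spec: PerturbationSpec, case_id: str = ""
) -> list[RoiMask]:
    """The original mask followed by ``n_variants`` perturbed alternatives."""
    variants = [mask]
    for v in range(1, spec.n_variants + 1):
        variants.append(perturb_mask(mask, spec, v, case_id=case_id))
    return variants
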