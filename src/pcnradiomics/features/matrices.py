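"""Shared texture-matrix container and 3D direction/offset utilities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TextureMatrix", "DIRECTIONS_13", "shift_array"]

#: the 13 unique direction vectors among the 26 neighbours of a 3D voxel
#: (one representative per +/- pair, lexicographically positive)
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass
class TextureMatrix:
    """Counts (or probabilities) indexed by gray level x second index."""

    kind: str  # {GLCM, GLRLM, GLSZM, NGTDM}
    matrix: np.ndarray
    params: dict = field(default_factory=dict)

    def probabilities(self) -> np.ndarray:
        total = self.matrix.sum()
        return self.matrix / total if total > 0 else self.matrix


def shift_array(a: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + offset], with ``fill`` outside the array bounds."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, d in zip(a.shape, offset):
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    out[tuple(dst)] = a[tuple(src)]
    return out
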