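"""Gray-level size-zone matrix and its thirteen features.

A zone is a 26-connected component of equal-level voxels inside the ROI;
the matrix is indexed (gray level, zone size).  GLV — the feature family
member selected in the wavelet LLL subband by the motivating analysis — is
the probability-weighted variance of the zone gray levels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume_io import QuantizedRoi
from .matrices import TextureMatrix

__all__ = ["glszm", "glszm_features", "GLSZM_FEATURES"]

GLSZM_FEATURES = (
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def glszm(q: QuantizedRoi) -> TextureMatrix:
    lev = q.levels
    n_vox = int((lev > 0).sum())
    zones: list[tuple[int, int]] = []  # (level, size)
    for g in np.unique(lev[lev > 0]):
        labelled, n = ndimage.label(lev == g, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((q.n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", counts, {"n_voxels": n_vox,
                                           "connectivity": 26})


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    z = m.matrix
    nz = z.sum()
    p = z / nz
    ng, ns = z.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    zi = z.sum(axis=1)
    zj = z.sum(axis=0)
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "SZE": float(np.sum(p / j ** 2)),
        "LZE": float(np.sum(p * j ** 2)),
        "GLN": float(np.sum(zi ** 2) / nz),
        "ZSN": float(np.sum(zj ** 2) / nz),
        "ZP": float(nz / m.params["n_voxels"]),
        "LGZE": float(np.sum(p / i ** 2)),
        "HGZE": float(np.sum(p * i ** 2)),
        "SZLGE": float(np.sum(p / (i ** 2 * j ** 2))),
        "SZHGE": float(np.sum(p * i ** 2 / j ** 2)),
        "LZLGE": float(np.sum(p * j ** 2 / i ** 2)),
        "LZHGE": float(np.sum(p * i ** 2 * j ** 2)),
        "GLV": float(np.sum(p * (i - mu_i) ** 2)),
        "ZSV": float(np.sum(p * (j - mu_j) ** 2)),
    }
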