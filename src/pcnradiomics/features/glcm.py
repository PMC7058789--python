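"""Gray-level co-occurrence matrix and its nine features.

Co-occurrences are counted over the 13 unique 3D direction offsets at the
configured distance, in both orderings (the matrix is symmetric by
construction), restricted to voxel pairs lying inside the ROI, summed over
directions and normalized once.
"""

from __future__ import annotations

import numpy as np

from ..errors import NoPairsError
from ..volume_io import QuantizedRoi
from .matrices import DIRECTIONS_13, TextureMatrix, shift_array

__all__ = ["glcm", "glcm_features", "GLCM_FEATURES"]

GLCM_FEATURES = (
    "Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
    "SumAverage", "Variance", "Dissimilarity", "Autocorrelation",
)

_EPS = 1e-12


def glcm(q: QuantizedRoi, distance: int = 1) -> TextureMatrix:
    ng = q.n_levels
    lev = q.levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        nb = shift_array(lev, off)
        both = (lev > 0) & (nb > 0)
        if not both.any():
            continue
        a = lev[both] - 1
        b = nb[both] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    if counts.sum() == 0:
        raise NoPairsError("ROI contains no co-occurring voxel pairs")
    return TextureMatrix("GLCM", counts, {"distance": distance,
                                          "n_directions": 13})


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    p = m.probabilities()
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sig2 = float(np.sum((i - mu) ** 2 * px))
    nz = p[p > 0]
    if sig2 > _EPS:
        corr = float((np.sum(ii * jj * p) - mu * mu) / sig2)
    else:
        corr = 1.0  # single-level ROI: perfectly correlated by convention
    return {
        "Energy": float(np.sum(p ** 2)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Entropy": float(-np.sum(nz * np.log2(nz))),
        "Homogeneity": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Correlation": corr,
        "SumAverage": float(np.sum((ii + jj) * p)),
        "Variance": float(np.sum((ii - mu) ** 2 * p)),
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "Autocorrelation": float(np.sum(ii * jj * p)),
    }
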