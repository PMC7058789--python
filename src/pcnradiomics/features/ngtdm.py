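"""Neighborhood gray-tone difference matrix and its five features.

For each gray level i, s(i) sums |i - mean level of the 26-neighborhood|
over the ROI voxels at level i, with neighborhoods restricted to the ROI
(voxels whose neighborhood contains no ROI voxel are excluded from the
counts).  Features follow the classic coarseness / contrast / busyness /
complexity / strength definitions; denominators that vanish on degenerate
(single-level) ROIs are floored at eps = 1e-12 for coarseness and defined
as 0 elsewhere so phantom edge cases stay finite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume_io import QuantizedRoi
from .matrices import TextureMatrix

__all__ = ["ngtdm", "ngtdm_features", "NGTDM_FEATURES"]

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EPS = 1e-12


def ngtdm(q: QuantizedRoi) -> TextureMatrix:
    lev = q.levels.astype(np.float64)
    roi = (q.levels > 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(lev * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(roi, kernel, mode="constant", cval=0.0)
    valid = (roi > 0) & (nb_cnt > 0)
    abar = np.zeros_like(lev)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    ng = q.n_levels
    s = np.zeros(ng, dtype=np.float64)
    n = np.zeros(ng, dtype=np.float64)
    lv = q.levels[valid]
    diff = np.abs(q.levels[valid].astype(np.float64) - abar[valid])
    np.add.at(s, lv - 1, diff)
    np.add.at(n, lv - 1, 1.0)
    # matrix rows: [n_i, p_i, s_i]
    total = n.sum()
    p = n / total if total > 0 else n
    mat = np.stack([n, p, s], axis=1)
    return TextureMatrix("NGTDM", mat, {"n_valid": int(total)})


def ngtdm_features(m: TextureMatrix) -> dict[str, float]:
    n_i, p_i, s_i = m.matrix[:, 0], m.matrix[:, 1], m.matrix[:, 2]
    ng = m.matrix.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    n_total = n_i.sum()
    ngp = int(present.sum())

    ps = float(np.sum(p_i * s_i))
    coarseness = 1.0 / max(ps, _EPS)

    ii = i[present][:, None]
    jj = i[present][None, :]
    pi = p_i[present][:, None]
    pj = p_i[present][None, :]
    si = s_i[present][:, None]
    sj = s_i[present][None, :]

    if ngp > 1:
        contrast = float(np.sum(pi * pj * (ii - jj) ** 2)
                         / (ngp * (ngp - 1)) * s_i.sum() / n_total)
        denom = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = ps / denom if denom > _EPS else 0.0
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj)
                                  / (pi + pj)) / n_total)
        s_sum = float(s_i.sum())
        strength = (float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_sum
                    if s_sum > _EPS else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
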