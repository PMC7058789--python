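"""Gray-level run-length matrix and its thirteen features.

Runs of consecutive equal-level ROI voxels are scanned along the 13 unique
3D directions; a run is truncated wherever the line leaves the ROI.  The
per-direction matrices are merged by summation before normalization, so RP
(run percentage) is normalized by voxel count times the number of scanned
directions to stay in (0, 1].
"""

from __future__ import annotations

import numpy as np

from ..volume_io import QuantizedRoi
from .matrices import DIRECTIONS_13, TextureMatrix, shift_array

__all__ = ["glrlm", "glrlm_features", "GLRLM_FEATURES"]

GLRLM_FEATURES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)


def _runs_one_direction(lev: np.ndarray, d: tuple[int, int, int]):
    """(levels, lengths) of all runs along direction d, truncated at the ROI."""
    inroi = lev > 0
    nxt = shift_array(lev, d)
    # E[v]: the run containing v continues at v + d
    extend = inroi & (nxt == lev) & (nxt > 0)
    prev = shift_array(lev, tuple(-c for c in d))
    cont_prev = inroi & (prev == lev) & (prev > 0)
    start = inroi & ~cont_prev
    lengths = np.ones(lev.shape, dtype=np.int64)
    term = extend & start  # runs extending at least one step beyond the start
    k = 1
    while term.any():
        lengths[term] += 1
        k += 1
        step = tuple(k_ * c for k_, c in zip((k - 1,) * 3, d))
        term = term & shift_array(extend, step)
    return lev[start], lengths[start]


def glrlm(q: QuantizedRoi, directions=None) -> TextureMatrix:
    dirs = tuple(directions) if directions is not None else DIRECTIONS_13
    lev = q.levels
    max_len = max(lev.shape)
    counts = np.zeros((q.n_levels, max_len), dtype=np.float64)
    for d in dirs:
        levels, lengths = _runs_one_direction(lev, d)
        np.add.at(counts, (levels - 1, lengths - 1), 1.0)
    used = counts.any(axis=0)
    last = int(np.nonzero(used)[0].max()) + 1 if used.any() else 1
    return TextureMatrix("GLRLM", counts[:, :last],
                         {"n_directions": len(dirs),
                          "n_voxels": int((lev > 0).sum())})


def glrlm_features(m: TextureMatrix) -> dict[str, float]:
    r = m.matrix
    nr = r.sum()
    p = r / nr
    ng, nl = r.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    n_vox = m.params["n_voxels"]
    n_dir = m.params["n_directions"]
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "SRE": float(np.sum(p / j ** 2)),
        "LRE": float(np.sum(p * j ** 2)),
        "GLN": float(np.sum(ri ** 2) / nr),
        "RLN": float(np.sum(rj ** 2) / nr),
        "RP": float(nr / (n_vox * n_dir)),
        "LGRE": float(np.sum(p / i ** 2)),
        "HGRE": float(np.sum(p * i ** 2)),
        "SRLGE": float(np.sum(p / (i ** 2 * j ** 2))),
        "SRHGE": float(np.sum(p * i ** 2 / j ** 2)),
        "LRLGE": float(np.sum(p * j ** 2 / i ** 2)),
        "LRHGE": float(np.sum(p * i ** 2 * j ** 2)),
        "GLV": float(np.sum(p * (i - mu_i) ** 2)),
        "RLV": float(np.sum(p * (j - mu_j) ** 2)),
    }
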