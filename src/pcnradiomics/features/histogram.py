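"""First-order histogram features of the quantized ROI.

All moments are taken over the discrete level probabilities p(i),
i = 1..n_levels; entropy is in bits.  A zero-variance ROI has skewness and
kurtosis defined as 0 so degenerate phantoms stay finite.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import QuantizedRoi

__all__ = ["histogram_features", "HISTOGRAM_FEATURES"]

HISTOGRAM_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Energy", "Entropy", "Uniformity",
)


def histogram_features(q: QuantizedRoi) -> dict[str, float]:
    p = q.level_probabilities
    i = np.arange(1, q.n_levels + 1, dtype=np.float64)
    mean = float(np.sum(i * p))
    var = float(np.sum((i - mean) ** 2 * p))
    if var > 0:
        skew = float(np.sum((i - mean) ** 3 * p) / var ** 1.5)
        kurt = float(np.sum((i - mean) ** 4 * p) / var ** 2)
    else:
        skew = kurt = 0.0
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    uniformity = float(np.sum(p ** 2))
    # normalized second raw moment of the level values (distinct from
    # uniformity, which is the sum of squared probabilities)
    energy = float(np.sum(i ** 2 * p))
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "Entropy": entropy,
        "Uniformity": uniformity,
    }
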