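"""Out-of-bag bookkeeping for scikit-learn forests.

scikit-learn regenerates each tree's bootstrap from the tree's stored
random state rather than storing the indices; this thin wrapper recovers
the out-of-bag rows per tree (and tolerates the signature change that
added ``sample_weight``).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble._forest import _generate_unsampled_indices

__all__ = ["oob_indices"]


def oob_indices(tree, n_samples: int) -> np.ndarray:
    """Indices of the samples the given tree never saw during fitting."""
    try:
        return _generate_unsampled_indices(tree.random_state, n_samples,
                                           n_samples, None)
    except TypeError:  # older signature without sample_weight
        return _generate_unsampled_indices(tree.random_state, n_samples,
                                           n_samples)
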