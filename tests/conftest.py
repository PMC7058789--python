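"""Shared fixtures: small phantom cases and quantized-ROI builders."""

from __future__ import annotations

import numpy as np
import pytest

from pcnradiomics.phantom import default_class_specs, generate_tumor
from pcnradiomics.volume_io import ImageVolume, QuantizedRoi, RoiMask


def make_quantized(levels: np.ndarray, n_levels: int) -> QuantizedRoi:
    """Wrap a raw integer level array (0 = background) as a QuantizedRoi."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = (levels > 0).astype(np.uint8)
    edges = np.arange(n_levels + 1, dtype=np.float64)
    return QuantizedRoi(levels, mask, n_levels, edges)


@pytest.fixture(scope="session")
def class_specs():
    return default_class_specs()


@pytest.fixture(scope="session")
def sca_case(class_specs):
    """One deterministic SCA phantom (volume, mask)."""
    return generate_tumor(class_specs["SCA"], seed=42)


@pytest.fixture()
def constant_case():
    """A constant-intensity volume with a small box ROI."""
    grid = np.full((12, 12, 8), 37.0)
    mask = np.zeros((12, 12, 8), dtype=np.uint8)
    mask[4:8, 4:8, 3:5] = 1
    spacing = (1.0, 1.0, 5.0)
    return ImageVolume(grid, spacing), RoiMask(mask, spacing)
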