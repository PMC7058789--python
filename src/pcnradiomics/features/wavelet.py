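"""Single-level 3D stationary wavelet decomposition into eight subbands.

The undecimated (stationary) transform keeps every subband on the input
grid, so the original ROI mask applies to all of them without resampling.
Subbands are labelled by the low/high filter applied along each axis in
(x, y, z) order: LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH.  The default
filter is the orthogonal 8-tap Daubechies-4 wavelet; with the normalized
transform the total subband energy equals the input energy (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ..errors import InvalidArgumentError
from ..volume_io import ImageVolume

__all__ = ["WaveletStack", "wavelet_decompose", "SUBBAND_LABELS"]

SUBBAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

DEFAULT_WAVELET = "db4"


@dataclass
class WaveletStack:
    subbands: dict[str, ImageVolume]
    wavelet: str
    level: int = 1

    def __post_init__(self):
        if set(self.subbands) != set(SUBBAND_LABELS):
            raise InvalidArgumentError("stack must hold exactly the 8 subbands")

    def __getitem__(self, label: str) -> ImageVolume:
        return self.subbands[label]


def wavelet_decompose(vol: ImageVolume, wavelet: str = DEFAULT_WAVELET) -> WaveletStack:
    w = pywt.Wavelet(wavelet)
    shape = vol.shape
    if any(n < w.dec_len for n in shape):
        raise InvalidArgumentError(
            f"volume shape {shape} smaller than the {w.dec_len}-tap filter support"
        )
    # the stationary transform needs even axis lengths; edge-pad and crop back
    pad = [(0, n % 2) for n in shape]
    data = np.pad(vol.grid, pad, mode="edge")
    coeffs = pywt.swtn(data, w, level=1, norm=True)[0]
    subbands = {}
    for key, arr in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        cropped = arr[: shape[0], : shape[1], : shape[2]]
        subbands[label] = ImageVolume(cropped, vol.spacing, vol.origin)
    return WaveletStack(subbands, wavelet)
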