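"""Whole-case feature extraction: resample, decompose, quantize, measure.

The default configuration resamples a case to a 1 x 1 x 5 mm grid, computes
the eight stationary-wavelet subbands, quantizes the ROI of the original
image and of every subband independently to 64 gray levels (subband value
ranges have nothing to do with HU), and measures the five feature families
on each of the nine images: 9 x 47 = 423 named features.  The name registry
is a pure function of the configuration, so tables from different runs are
joinable column-for-column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..volume_io import ImageVolume, RoiMask, quantize_roi, resample
from .glcm import GLCM_FEATURES, glcm, glcm_features
from .glrlm import GLRLM_FEATURES, glrlm, glrlm_features
from .glszm import GLSZM_FEATURES, glszm, glszm_features
from .histogram import HISTOGRAM_FEATURES, histogram_features
from .ngtdm import NGTDM_FEATURES, ngtdm, ngtdm_features
from .wavelet import DEFAULT_WAVELET, SUBBAND_LABELS, wavelet_decompose

__all__ = ["FeatureConfig", "feature_names", "extract_all", "extract_table"]

_FAMILIES = (
    ("Histogram", HISTOGRAM_FEATURES),
    ("GLCM", GLCM_FEATURES),
    ("GLRLM", GLRLM_FEATURES),
    ("GLSZM", GLSZM_FEATURES),
    ("NGTDM", NGTDM_FEATURES),
)


@dataclass(frozen=True)
class FeatureConfig:
    n_levels: int = 64
    glcm_distance: int = 1
    wavelet: str = DEFAULT_WAVELET
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    include_wavelet: bool = True


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """The frozen feature-name registry for a configuration."""
    prefixes = [""]
    if config.include_wavelet:
        prefixes += [f"{lab}_" for lab in SUBBAND_LABELS]
    names = []
    for pre in prefixes:
        for family, feats in _FAMILIES:
            names.extend(f"{pre}{family}_{f}" for f in feats)
    return names


def _image_features(img: ImageVolume, mask: RoiMask, config: FeatureConfig
                    ) -> dict[str, float]:
    q = quantize_roi(img, mask, config.n_levels)
    out = {}
    out.update({f"Histogram_{k}": v for k, v in histogram_features(q).items()})
    out.update({f"GLCM_{k}": v
                for k, v in glcm_features(glcm(q, config.glcm_distance)).items()})
    out.update({f"GLRLM_{k}": v for k, v in glrlm_features(glrlm(q)).items()})
    out.update({f"GLSZM_{k}": v for k, v in glszm_features(glszm(q)).items()})
    out.update({f"NGTDM_{k}": v for k, v in ngtdm_features(ngtdm(q)).items()})
    return out


def extract_all(vol: ImageVolume, mask: RoiMask,
                config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """Named feature vector for one case (one segmentation)."""
    vol, mask = resample(vol, mask, config.target_spacing)
    values = dict(_image_features(vol, mask, config))
    if config.include_wavelet:
        stack = wavelet_decompose(vol, config.wavelet)
        for label in SUBBAND_LABELS:
            sub = stack[label]
            values.update({f"{label}_{k}": v
                           for k, v in _image_features(sub, mask, config).items()})
    ordered = {name: float(values[name]) for name in feature_names(config)}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite features: {bad[:5]}...")
    return ordered


def extract_table(cases, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature table for (patient_id, volume, mask) triples."""
    rows = {}
    for pid, vol, mask in cases:
        rows[pid] = extract_all(vol, mask, config)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table[feature_names(config)]
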