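"""Counter-based random-stream derivation.

Every source of randomness in the pipeline (phantom cases, per-slice mask
perturbations, fold shuffles, forest bootstraps, shadow shuffles, network
inits) draws from a named substream derived from one master seed.  Streams
are keyed by ``(master_seed, *keys)`` where string keys are hashed with
CRC-32, so the stream a consumer sees is independent of the order in which
other consumers draw — reproducibility does not depend on generation order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def _key_ints(keys) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        elif isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            raise TypeError(f"stream key must be int or str, got {type(k)!r}")
    return out


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``."""
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *_key_ints(keys)])
    return np.random.default_rng(seq)


def stream_seed(master_seed: int, *keys) -> int:
    """A 31-bit integer seed for libraries that take one (e.g. scikit-learn)."""
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *_key_ints(keys)])
    return int(seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
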