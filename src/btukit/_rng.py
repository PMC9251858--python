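"""Deterministic RNG stream derivation.

All randomness in the package flows from a single user seed.  Child streams
are derived from stable string keys so that, e.g., the PERMANOVA permutations
of a given BTU are identical across the Bray-Curtis and Jaccard runs.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def child_seed(seed: int, *keys) -> int:
    """Derive a deterministic child seed (< 2**31) from a seed and keys."""
    h = zlib.crc32(repr(tuple(keys)).encode("utf8"))
    return int((int(seed) * 2654435761 + h) % _MOD)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """A `numpy` Generator seeded from ``child_seed(seed, *keys)``."""
    return np.random.default_rng(child_seed(seed, *keys))
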