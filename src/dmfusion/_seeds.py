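"""Deterministic seed derivation.

A single master seed drives every stochastic stage. Stage- and
iteration-level generators are derived by hashing the master seed together
with a tuple of string/int keys, so stages are statistically independent
yet individually reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "spawn_rng"]

_MOD = 2**31 - 1


def derive_seed(master: int, *keys: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a key path."""
    digest = zlib.crc32(repr((int(master),) + tuple(keys)).encode("utf-8"))
    # crc32 alone has only 32 bits of state; fold the master back in so
    # distinct masters with colliding key reprs stay distinct.
    return int((digest * 2654435761 + int(master)) % _MOD)


def spawn_rng(master: int, *keys: object) -> np.random.Generator:
    """A numpy Generator seeded from ``derive_seed(master, *keys)``."""
    return np.random.default_rng(derive_seed(master, *keys))
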