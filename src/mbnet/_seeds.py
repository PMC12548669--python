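"""Deterministic seed derivation.

Every stochastic stage draws from a child of a single master seed via
``numpy.random.SeedSequence`` spawn keys, so one integer reproduces a whole
experiment and each stage's effective seed can be recorded in run metadata.
String key components are hashed to stable 32-bit integers.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def _key_part(part) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf8"))
    return int(part) & 0xFFFFFFFF


def child_seed(master: int, *key) -> int:
    """A reproducible sub-seed (< 2**31) for stage ``key`` of run ``master``."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(_key_part(p) for p in key))
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master: int, *key) -> np.random.Generator:
    """Generator seeded by :func:`child_seed` of the same key."""
    return np.random.default_rng(child_seed(master, *key))
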