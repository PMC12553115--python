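"""Seed management.

All randomness in the package flows from a single integer seed. Sub-streams
are derived by hashing string keys into a :class:`numpy.random.SeedSequence`
spawn key, so each pipeline stage (and each participant within a stage) gets
an independent, reproducible stream that does not depend on execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(key.encode("utf-8"))


def child_seed(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Derive a named sub-seed from a global seed and a path of keys."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Independent generator for the sub-stream named by ``keys``."""
    return np.random.default_rng(child_seed(seed, *keys))
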