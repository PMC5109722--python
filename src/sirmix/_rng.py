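"""Hierarchical seed derivation.

A master seed plus a path of string/number keys deterministically yields a
sub-seed, so changing the realization count of one pipeline stage does not
perturb the random streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(repr(key).encode())


def child_seed(master: int, *keys) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a master seed and keys."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1)[0] >> 1)
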