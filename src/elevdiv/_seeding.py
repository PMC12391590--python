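"""Deterministic seed substreams.

Every stochastic stage derives its own generator from one master seed plus a
tuple of string/int keys, so results do not depend on the order in which
stages run and re-running a single stage reproduces the full-run numbers.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``."""
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *(_key_to_int(k) for k in keys)])
    return np.random.default_rng(ss)


def spawn_seed(seed: int, *keys: str | int) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
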