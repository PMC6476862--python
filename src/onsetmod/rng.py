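"""Seed-substream management.

A single integer seed is expanded into independent, reproducible
substreams keyed by (op name, counters) via numpy's SeedSequence
spawn-key mechanism.  String keys are hashed with CRC32 so the mapping
is stable across processes and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_int(k) -> int:
    if isinstance(k, str):
        return zlib.crc32(k.encode("utf-8"))
    return int(k) & 0xFFFFFFFF


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream of ``seed`` identified by ``keys``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key_int(k) for k in keys))
    return np.random.default_rng(ss)


def spawn_int(seed: int, *keys) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    return int(substream(seed, *keys).integers(0, 2**31 - 1))
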