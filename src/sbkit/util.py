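"""Seed plumbing: one global seed, per-stage derived substreams."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, *names: str) -> np.random.Generator:
    """Derive an independent, reproducible stream for a named stage.

    The stream depends only on (seed, names), so adding a stage never
    shifts another stage's randomness.
    """
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
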