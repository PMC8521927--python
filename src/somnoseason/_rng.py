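"""Seed management.

All stochastic modules draw from named substreams of a single master seed so
that each pipeline stage (meteorology, cohort, acceleration, bootstrap) can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable integer seed (< 2**31) for the named substream."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and the substream ``name``."""
    return np.random.default_rng(child_seed(seed, name))
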