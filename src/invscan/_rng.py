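"""Deterministic RNG stream derivation.

A single top-level seed is forked into per-stage / per-strain streams by a
stable string label, so regenerating one stage of a run reproduces exactly
the same stream regardless of which other stages ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np


def fork_rng(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for ``seed`` specialized by a label path."""
    key = [seed & 0x7FFFFFFF] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(key))
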