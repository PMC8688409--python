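"""Seed-stream derivation.

Every stochastic operation in the package derives its own independent
generator from (root seed, operation label), so adding or removing one
stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def _label_key(label: str) -> int:
    # crc32 is stable across platforms and Python versions; mask to < 2**31
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def stream(root_seed: int, label: str) -> np.random.Generator:
    """Return an independent ``numpy`` generator for (root_seed, label)."""
    if not isinstance(root_seed, (int, np.integer)):
        raise TypeError(f"root seed must be an integer, got {root_seed!r}")
    ss = np.random.SeedSequence(entropy=int(root_seed) & 0x7FFFFFFF,
                                spawn_key=(_label_key(label),))
    return np.random.default_rng(ss)
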