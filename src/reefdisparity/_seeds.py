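"""Deterministic child-seed derivation.

Every stochastic operation in the package takes an explicit seed or Generator.
Pipelines derive per-(stage, unit) child seeds from one master seed by hashing
the token path, so per-species results do not depend on processing order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng", "as_rng"]


def child_seed(master_seed: int, *tokens: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and tokens.

    The same (master_seed, tokens) always yields the same child, and distinct
    token paths yield (with overwhelming probability) distinct streams.
    """
    h = zlib.crc32(repr(tuple(str(t) for t in tokens)).encode())
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(h,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *tokens))


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Accept a seed, a Generator, or None, and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
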