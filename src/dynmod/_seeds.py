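"""Deterministic RNG derivation.

Every stochastic stage derives its generator from (master seed, stage
name, subject id, ...) so results are reproducible independent of
execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def derive_seed(master_seed: int, *keys: object) -> np.random.SeedSequence:
    """SeedSequence keyed on the master seed plus arbitrary stage keys."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Generator keyed on (master seed, stage keys); stable across runs."""
    return np.random.default_rng(derive_seed(master_seed, *keys))
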