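"""Deterministic sub-seed derivation.

Every stochastic stage draws from a Generator keyed by a master seed plus a
stable tag path (stage name, region, grid index, replicate index).  Adding a
region or grid point therefore never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed_sequence", "rng_for"]


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0x7FFFFFFF
    return zlib.crc32(str(tag).encode("utf-8")) & 0x7FFFFFFF


def derive_seed_sequence(master_seed: int, *tags) -> np.random.SeedSequence:
    """SeedSequence for ``(master_seed, *tags)``; tags may be ints or strings."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.SeedSequence(entropy)


def rng_for(master_seed: int, *tags) -> np.random.Generator:
    """A PCG64 Generator keyed by the master seed and a stable tag path."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *tags))
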