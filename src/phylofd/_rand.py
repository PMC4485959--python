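"""Seed plumbing: accept ints, Generators or SeedSequences everywhere."""

from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, k: int) -> list:
    """k independent child seeds from an int, Generator or SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(k)
    if isinstance(seed, np.random.Generator):
        return [int(seed.integers(2**31)) for _ in range(k)]
    return np.random.SeedSequence(seed).spawn(k)
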