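"""Seed plumbing: one seeded generator per invocation, fanned out to subsystems."""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

SeedLike = Union[None, int, np.random.SeedSequence, np.random.Generator]


def as_generator(seed: SeedLike = None) -> np.random.Generator:
    """Coerce ints/SeedSequences to a Generator; pass Generators through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed: SeedLike, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed.

    Children are reproducible functions of the parent seed alone, so sweeps
    are deterministic and embarrassingly parallelizable.
    """
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq.spawn(n)  # type: ignore[union-attr]
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed.spawn(n)
    else:
        ss = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in ss]


def derive_int(seed: SeedLike, cap: int = 2**31 - 1) -> int:
    """A small positive integer seed derived from any seed-like input."""
    return int(as_generator(seed).integers(1, cap))
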