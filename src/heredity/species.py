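"""Synthetic species populations with a known number of heritable states.

Each species is a binary prototype vector of length ``n_features`` with a
fraction ``f1`` of bits set.  An end-state observation is drawn by picking a
species according to its abundance and flipping each bit independently with
probability ``m`` (mutation).  With f1 = 0.5, m = 0.05 and 1000 features the
expected Euclidean distance between members of two different species is
sqrt(2 f1 (1-f1) N_f) ≈ 22 while members of the same species sit ≈ 10 apart,
so states are well clustered; other corners of (f1, m) space make the
problem progressively harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .data import ObservationMatrix
from .rng import as_generator

__all__ = [
    "SpeciesConfig",
    "SpeciesSet",
    "geometric_abundances",
    "make_species_set",
    "sample_population",
    "heterogeneous_config",
]

FloatOrPerFeature = Union[float, Sequence[float], np.ndarray]


@dataclass
class SpeciesConfig:
    """Generator configuration.

    ``f1`` and ``m`` may be scalars or per-feature arrays of length
    ``n_features`` (heterogeneous feature statistics).

    ``abundance`` controls how rows are allocated to species:

    - "uniform": balanced allocation — every species contributes
      floor(N_P/N_S) rows (the remainder spread over distinct random
      species) and row order is shuffled.  This is the base case in which
      species are represented equally, with no abundance fluctuations.
    - "multinomial": i.i.d. equal-probability draws, so occupancies
      fluctuate Poisson-like (rare species may get 1-2 rows, which
      measurably degrades detection at large N_S).
    - "geometric": i.i.d. draws with
      p_i = (1 - 1/N_S)^(i-1) / N_S for i <= N_S - 1 and
      p_{N_S} = (1 - 1/N_S)^(N_S - 1), under which the most/least common
      abundance ratio equals N_S - 1.
    """

    n_species: int
    n_features: int
    n_rows: int
    f1: FloatOrPerFeature = 0.5
    m: FloatOrPerFeature = 0.05
    abundance: str = "uniform"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_features < 1 or self.n_rows < 1:
            raise ValueError("n_species, n_features and n_rows must be positive")
        self.f1 = self._per_feature(self.f1, "f1", low=0.0, high=1.0, open_interval=True)
        self.m = self._per_feature(self.m, "m", low=0.0, high=0.5, open_interval=False)
        if self.abundance not in {"uniform", "multinomial", "geometric"}:
            raise ValueError("abundance must be 'uniform', 'multinomial' or 'geometric'")

    def _per_feature(self, value, name, low, high, open_interval) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n_features, float(arr))
        if arr.shape != (self.n_features,):
            raise ValueError(f"{name} must be a scalar or length-n_features array")
        if open_interval:
            ok = np.all((arr > low) & (arr < high))
        else:
            ok = np.all((arr >= low) & (arr <= high))
        if not ok:
            bounds = f"({low}, {high})" if open_interval else f"[{low}, {high}]"
            raise ValueError(f"{name} must lie in {bounds}")
        return arr


@dataclass
class SpeciesSet:
    """The ground truth: binary prototypes and their sampling probabilities."""

    prototypes: np.ndarray  # (n_species, n_features), entries in {0, 1}
    abundance_probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes)
        if not np.isin(self.prototypes, (0, 1)).all():
            raise ValueError("prototype entries must be 0 or 1")
        if self.abundance_probs is None:
            n = self.prototypes.shape[0]
            self.abundance_probs = np.full(n, 1.0 / n)
        self.abundance_probs = np.asarray(self.abundance_probs, dtype=float)
        if abs(self.abundance_probs.sum() - 1.0) > 1e-12:
            raise ValueError("abundance_probs must sum to 1")

    @property
    def n_species(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[1]


def geometric_abundances(n_species: int) -> np.ndarray:
    """p_i = (1-1/N_S)^(i-1)/N_S for i < N_S; p_{N_S} = (1-1/N_S)^(N_S-1)."""
    if n_species < 1:
        raise ValueError("n_species must be positive")
    if n_species == 1:
        return np.array([1.0])
    q = 1.0 - 1.0 / n_species
    i = np.arange(1, n_species + 1)
    p = q ** (i - 1) / n_species
    p[-1] = q ** (n_species - 1)
    return p


def make_species_set(config: SpeciesConfig, seed=None) -> SpeciesSet:
    """Draw prototypes i.i.d. per feature with P(bit = 1) = f1."""
    rng = as_generator(seed if seed is not None else config.seed)
    prototypes = (
        rng.random((config.n_species, config.n_features)) < config.f1[None, :]
    ).astype(np.int8)
    if config.abundance == "geometric":
        probs = geometric_abundances(config.n_species)
    else:
        probs = np.full(config.n_species, 1.0 / config.n_species)
    return SpeciesSet(prototypes, probs)


def sample_population(
    species: SpeciesSet, config: SpeciesConfig, seed=None
) -> ObservationMatrix:
    """Draw ``n_rows`` end-states: allocate each row a species according to
    the abundance mode, then flip each bit independently with probability m.
    Row metadata records the true species index."""
    rng = as_generator(seed if seed is not None else config.seed)
    if config.abundance == "uniform":
        base = config.n_rows // species.n_species
        picks = np.tile(np.arange(species.n_species), base)
        remainder = config.n_rows - base * species.n_species
        if remainder:
            extra = rng.choice(species.n_species, size=remainder, replace=False)
            picks = np.concatenate([picks, extra])
        rng.shuffle(picks)
    else:
        picks = rng.choice(species.n_species, size=config.n_rows, p=species.abundance_probs)
    rows = species.prototypes[picks].astype(np.int8)
    flips = rng.random((config.n_rows, config.n_features)) < config.m[None, :]
    rows = np.where(flips, 1 - rows, rows)
    return ObservationMatrix(rows.astype(float), row_meta=picks.tolist())


def heterogeneous_config(
    n_features: int,
    f1_groups: Optional[Sequence[Tuple[float, float]]] = None,
    m_groups: Optional[Sequence[Tuple[float, float]]] = None,
    **kwargs,
) -> SpeciesConfig:
    """Expand (fraction, value) group specs into per-feature f1/m arrays.

    Groups occupy contiguous feature blocks in the stated proportions (the
    metric is rotation invariant, so column order is immaterial).  Fractions
    in each list must sum to 1.  Crossed designs are expressed by listing the
    product blocks explicitly, e.g. four blocks of fraction 0.25 crossing
    f1 in {0.05, 0.5} with m in {0.05, 0.2}.
    """

    def expand(groups, default):
        if groups is None:
            return default
        fractions = np.array([g[0] for g in groups], dtype=float)
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        sizes = np.floor(fractions * n_features).astype(int)
        sizes[-1] = n_features - sizes[:-1].sum()  # absorb rounding in the last block
        out = np.empty(n_features)
        start = 0
        for size, (_, value) in zip(sizes, groups):
            out[start : start + size] = value
            start += size
        return out

    f1 = expand(f1_groups, kwargs.pop("f1", 0.5))
    m = expand(m_groups, kwargs.pop("m", 0.05))
    return SpeciesConfig(n_features=n_features, f1=f1, m=m, **kwargs)
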