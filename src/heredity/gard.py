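"""GARD: compositional heredity in catalytically growing lipid vesicles.

A vesicle is a count vector over ``n_lipid_types`` lipid species.  Lipids
join at a rate set by mutual catalysis through a random affinity matrix
beta (lognormal entries; the spread of the distribution controls how much
heredity the model exhibits).  At size ``n_max`` a vesicle splits into two
random halves — replication without a genome, at low fidelity.  The
heritable states of the model are its compositional attractors
("compotypes").

Selection pressure targets a composition t on the simplex by scaling row i
of beta by (1 + sigma * t_i): lipids the target favours become better
catalysed, shifting which attractor wins the population competition.  The
metric observes only system-averaged compositions, one row per sampled
pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA

from ._gard_core import simulate_core
from .data import ObservationMatrix
from .rng import as_generator, derive_int

__all__ = [
    "GardConfig",
    "Vesicle",
    "generate_beta",
    "sample_target",
    "apply_pressure",
    "grow_weights",
    "grow_step",
    "divide",
    "simulate_population",
    "gard_observation_matrix",
    "project_trajectories",
]

#: Lognormal parameters (mu, sigma of log-entries) for the affinity matrix;
#: the canonical choice in the GARD literature.
DEFAULT_BETA_LAW = ("lognormal", -4.0, 4.0)


@dataclass
class GardConfig:
    n_lipid_types: int = 100
    n_max: int = 50
    population: int = 10
    generations: int = 100
    sigma: float = 50.0
    beta_law: Tuple = DEFAULT_BETA_LAW
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_max % 2 != 0:
            raise ValueError("n_max must be even (children have size n_max/2)")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.population < 1 or self.generations < 1 or self.n_lipid_types < 2:
            raise ValueError("population, generations and n_lipid_types must be positive")


@dataclass
class Vesicle:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("lipid counts must be nonnegative")

    @property
    def size(self) -> int:
        return int(self.counts.sum())


def generate_beta(
    n_lipid_types: int, beta_law: Tuple = DEFAULT_BETA_LAW, seed=None
) -> np.ndarray:
    """Seeded i.i.d. positive affinity matrix from the configured law."""
    rng = as_generator(seed)
    kind = beta_law[0]
    if kind == "lognormal":
        mu, sig = float(beta_law[1]), float(beta_law[2])
        if sig <= 0:
            raise ValueError("lognormal sigma must be positive")
        return rng.lognormal(mean=mu, sigma=sig, size=(n_lipid_types, n_lipid_types))
    if kind == "uniform":
        low, high = float(beta_law[1]), float(beta_law[2])
        if low <= 0 or high <= low:
            raise ValueError("uniform law requires 0 < low < high")
        return rng.uniform(low, high, size=(n_lipid_types, n_lipid_types))
    raise ValueError(f"unknown beta law {kind!r}")


def sample_target(n_lipid_types: int, seed=None, sparse: Optional[int] = None) -> np.ndarray:
    """A selection target on the simplex: symmetric Dirichlet(1) by default,
    or concentrated on ``sparse`` random lipid types."""
    rng = as_generator(seed)
    if sparse is None:
        t = rng.dirichlet(np.ones(n_lipid_types))
    else:
        if not 1 <= sparse <= n_lipid_types:
            raise ValueError("sparse must be in [1, n_lipid_types]")
        t = np.zeros(n_lipid_types)
        support = rng.choice(n_lipid_types, size=sparse, replace=False)
        t[support] = rng.dirichlet(np.ones(sparse))
    return t


def apply_pressure(beta: np.ndarray, target: np.ndarray, sigma: float) -> np.ndarray:
    """Scale row i of beta by (1 + sigma * t_i); returns a copy."""
    beta = np.asarray(beta, dtype=float)
    target = np.asarray(target, dtype=float)
    if target.shape != (beta.shape[0],):
        raise ValueError("target length must match the affinity matrix dimension")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if abs(target.sum() - 1.0) > 1e-9 or np.any(target < 0):
        raise ValueError("target must be a probability vector")
    return beta * (1.0 + sigma * target)[:, None]


def grow_weights(counts: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Addition propensity per lipid type: w_i = 1 + (1/size) * (beta @ n)_i.

    The constant 1 is the uncatalysed background incorporation from a uniform
    ambient supply; an empty vesicle therefore grows uniformly.
    """
    counts = np.asarray(counts, dtype=float)
    size = counts.sum()
    if size == 0:
        return np.ones(beta.shape[0])
    return 1.0 + (beta @ counts) / size


def grow_step(vesicle: Vesicle, beta: np.ndarray, rng, n_max: Optional[int] = None) -> Vesicle:
    """Add one lipid, type drawn proportional to the growth weights."""
    if n_max is not None and vesicle.size >= n_max:
        raise ValueError("vesicle is at n_max; it must divide before growing")
    rng = as_generator(rng)
    w = grow_weights(vesicle.counts, beta)
    t = rng.choice(beta.shape[0], p=w / w.sum())
    counts = vesicle.counts.copy()
    counts[t] += 1
    return Vesicle(counts)


def divide(vesicle: Vesicle, rng) -> Tuple[Vesicle, Vesicle]:
    """Split into two exact halves; lipids assigned without replacement
    (multivariate hypergeometric), conserving every type."""
    size = vesicle.size
    if size % 2 != 0:
        raise ValueError("vesicle size must be even to divide")
    rng = as_generator(rng)
    first = rng.multivariate_hypergeometric(vesicle.counts, size // 2)
    return Vesicle(first), Vesicle(vesicle.counts - first)


def simulate_population(
    beta: np.ndarray,
    config: GardConfig,
    target: Optional[np.ndarray] = None,
    seed=None,
    record_generations: Optional[int] = None,
) -> np.ndarray:
    """Grow a population of P vesicles under one selection pressure.

    The pressure (if any) is folded into beta, then growth events are drawn
    across the population proportional to each vesicle's total addition
    propensity.  On division both children enter and one uniformly random
    member of the P+1 candidates is culled, keeping the population at P —
    lineages compete and the fastest-growing composition excludes the rest.
    P = 1 reduces to the serial-transfer protocol of a single lineage.

    Runs for ``generations`` division events per capita and returns the
    population-mean normalized composition (sums to 1).  With
    ``record_generations`` set, also returns the mean-composition trajectory
    sampled every that many generations, as (composition, trajectory).
    """
    rng = as_generator(seed if seed is not None else config.seed)
    beta_eff = np.asarray(beta, dtype=float)
    if target is not None:
        beta_eff = apply_pressure(beta_eff, target, config.sigma)
    n_divisions = config.generations * config.population
    if record_generations is not None and record_generations > 0:
        interval = record_generations * config.population
        n_records = n_divisions // interval
    else:
        interval = 0
        n_records = 0
    record = np.zeros((n_records, config.n_lipid_types))
    comp = simulate_core(
        np.ascontiguousarray(beta_eff),
        config.n_max,
        config.population,
        n_divisions,
        derive_int(rng, cap=2**31 - 1),
        record,
        interval,
    )
    if interval > 0:
        return comp, record
    return comp


def gard_observation_matrix(
    beta: np.ndarray, config: GardConfig, n_pressures: int, seed=None
) -> ObservationMatrix:
    """One observation row per sampled selection pressure.

    Targets are drawn independently on the simplex; each is simulated to its
    long-time population and the system-averaged composition recorded.
    """
    if n_pressures < 2:
        raise ValueError("need at least 2 selection pressures")
    rng = as_generator(seed if seed is not None else config.seed)
    rows = np.empty((n_pressures, config.n_lipid_types))
    for k in range(n_pressures):
        target = sample_target(config.n_lipid_types, rng)
        rows[k] = simulate_population(beta, config, target, seed=rng)
    labels = [f"lipid{i}" for i in range(config.n_lipid_types)]
    return ObservationMatrix(rows, feature_labels=labels)


def project_trajectories(
    trajectories: Sequence[np.ndarray],
    components: int = 2,
    grid: int = 20,
) -> dict:
    """Project state trajectories onto leading principal components and bin
    the mean flow field, for external streamline plotting.

    Fits a PCA on all states pooled, projects each trajectory, then bins the
    per-step displacement vectors on a ``grid`` x ``grid`` lattice over the
    occupied region (bin owned by the step's starting point).  Returns the
    projected trajectories, per-bin mean displacement, per-bin visit counts
    and the bin edges.
    """
    trajectories = [np.asarray(t, dtype=float) for t in trajectories]
    if any(t.ndim != 2 or t.shape[0] < 2 for t in trajectories):
        raise ValueError("each trajectory needs at least 2 time points")
    stacked = np.vstack(trajectories)
    if min(stacked.shape[0] - 1, stacked.shape[1]) < components:
        raise ValueError("not enough data for the requested number of components")
    pca = PCA(n_components=components)
    pca.fit(stacked)
    projected = [pca.transform(t) for t in trajectories]

    pooled = np.vstack(projected)
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    edges = [np.linspace(lo[d], lo[d] + span[d], grid + 1) for d in range(components)]
    flow_sum = np.zeros((grid,) * components + (components,))
    visits = np.zeros((grid,) * components, dtype=int)
    for path in projected:
        starts, steps = path[:-1], np.diff(path, axis=0)
        idx = tuple(
            np.clip(np.searchsorted(edges[d], starts[:, d], side="right") - 1, 0, grid - 1)
            for d in range(components)
        )
        np.add.at(flow_sum, idx, steps)
        np.add.at(visits, idx, 1)
    with np.errstate(invalid="ignore"):
        mean_flow = np.where(visits[..., None] > 0, flow_sum / np.maximum(visits, 1)[..., None], 0.0)
    return {
        "projected": projected,
        "mean_flow": mean_flow,
        "visits": visits,
        "edges": edges,
        "explained_variance": pca.explained_variance_,
    }
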