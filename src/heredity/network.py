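"""Clustered replication/mutation transition matrices and their dynamics.

The model is a quasispecies-style linear system: random walkers distributed
over nodes, moved by a weighted transition matrix whose outgoing weights at
node i sum to that node's replication rate r_i > 1.  Cluster structure is
imprinted by giving within-cluster links a pre-normalization weight
(1+gamma)/2 and between-cluster links (1-gamma)/2, so with gamma near 1 a
walker overwhelmingly stays inside its cluster and each cluster behaves as a
quasispecies exceeding the error threshold.  At long times competitive
exclusion hands the whole population to one cluster — which one depends on
the selection perturbation — so an ensemble of perturbed runs reveals the
cluster count to the metric.

Convention: ``weights[i, j]`` is the weight of the link from node j to node
i, so populations evolve as p <- W p and column j sums to r_j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import ObservationMatrix
from .rng import as_generator

__all__ = [
    "ClusteredNetwork",
    "DynamicsConfig",
    "build_network",
    "perturb_selection",
    "iterate_dynamics",
    "run_ensemble",
]


@dataclass
class ClusteredNetwork:
    weights: np.ndarray            # (n, n), weights[i, j] = from j to i
    cluster_labels: np.ndarray     # (n,), values in 0..n_clusters-1
    replication_rates: np.ndarray  # (n,), column sums of weights
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1

    def to_json(self, path) -> None:
        """Serialize as labels, rates and sparse (target, source, weight) triples."""
        i, j = np.nonzero(self.weights)
        payload = {
            "cluster_labels": self.cluster_labels.tolist(),
            "replication_rates": self.replication_rates.tolist(),
            "links": [
                [int(a), int(b), float(self.weights[a, b])] for a, b in zip(i, j)
            ],
            "params": self.params,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)


@dataclass
class DynamicsConfig:
    """Ensemble-dynamics parameters.

    Defaults are the standard protocol: 250 iterations per run, 1000 runs,
    each run reducing the replication rates of a random half of the nodes by
    1% (the selection perturbation) with an extra ±1% uniform rate noise
    resampled every iteration.
    """

    iterations: int = 250
    runs: int = 1000
    perturb_fraction: float = 0.5
    perturb_size: float = 0.01
    noise_amplitude: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.runs < 1:
            raise ValueError("iterations and runs must be positive")
        for name in ("perturb_fraction", "perturb_size", "noise_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def build_network(
    n_nodes: int,
    n_clusters: int,
    n_links: int,
    r0: float = 1.1,
    dr: float = 0.03,
    gamma: float = 0.999,
    seed=None,
    balanced: bool = False,
) -> ClusteredNetwork:
    """Four-step clustered-matrix construction.

    1. assign each node a cluster (uniform multinomial, or round-robin when
       ``balanced``) and a rate r_i = r0 + dr*eta_i with eta_i ~ U[-1, 1];
    2. give each node ``n_links`` random links to other nodes, sampled with
       replacement (repeated pairs sum their weights; no self-links);
    3. weight each link (1+gamma)/2 within-cluster, (1-gamma)/2 between;
    4. rescale each node's outgoing weights to sum to r_i.
    """
    if n_clusters > n_nodes:
        raise ValueError("n_clusters may not exceed n_nodes")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if n_links >= n_nodes:
        raise ValueError("n_links must be smaller than n_nodes")
    rng = as_generator(seed)
    if balanced:
        labels = np.arange(n_nodes) % n_clusters
    else:
        labels = rng.integers(0, n_clusters, size=n_nodes)
    eta = rng.uniform(-1.0, 1.0, size=n_nodes)
    rates = r0 + dr * eta

    # with-replacement targets among the other n-1 nodes
    raw = rng.integers(0, n_nodes - 1, size=(n_nodes, n_links))
    sources = np.repeat(np.arange(n_nodes), n_links)
    targets = raw.ravel()
    targets = targets + (targets >= sources)  # skip the source itself
    same = labels[targets] == labels[sources]
    link_w = np.where(same, (1.0 + gamma) / 2.0, (1.0 - gamma) / 2.0)
    weights = np.zeros((n_nodes, n_nodes))
    np.add.at(weights, (targets, sources), link_w)
    col_sums = weights.sum(axis=0)
    weights *= rates / col_sums
    return ClusteredNetwork(
        weights=weights,
        cluster_labels=labels,
        replication_rates=rates,
        params={
            "n_nodes": n_nodes,
            "n_clusters": n_clusters,
            "n_links": n_links,
            "r0": r0,
            "dr": dr,
            "gamma": gamma,
        },
    )


def perturb_selection(
    net: ClusteredNetwork, config: Optional[DynamicsConfig] = None, seed=None
) -> ClusteredNetwork:
    """Selection pressure: scale all outgoing weights of a random fraction of
    nodes by (1 - perturb_size), equivalent to reducing their r_i.  Returns a
    copy; the original network is untouched."""
    config = config or DynamicsConfig()
    rng = as_generator(seed)
    n = net.n_nodes
    k = int(np.floor(config.perturb_fraction * n))
    chosen = rng.choice(n, size=k, replace=False)
    scale = np.ones(n)
    scale[chosen] = 1.0 - config.perturb_size
    return ClusteredNetwork(
        weights=net.weights * scale[None, :],
        cluster_labels=net.cluster_labels.copy(),
        replication_rates=net.replication_rates * scale,
        params=dict(net.params),
    )


def iterate_dynamics(
    net: ClusteredNetwork,
    config: Optional[DynamicsConfig] = None,
    seed=None,
    p0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Iterate p <- W p with per-iteration multiplicative rate noise.

    Each iteration every node's outgoing weights are scaled by an independent
    (1 + u), u ~ U(-noise_amplitude, +noise_amplitude), then the matrix is
    applied and the population renormalized to sum 1 (a pure numerical
    convenience for a linear system).  Returns the final population vector.
    """
    config = config or DynamicsConfig()
    rng = as_generator(seed)
    n = net.n_nodes
    if p0 is None:
        p = rng.random(n)
    else:
        p = np.asarray(p0, dtype=float).copy()
    total = p.sum()
    if total <= 0:
        raise ValueError("initial population must have positive mass")
    p /= total
    w = net.weights
    a = config.noise_amplitude
    for _ in range(config.iterations):
        if a > 0:
            noise = 1.0 + rng.uniform(-a, a, size=n)
            p = w @ (noise * p)
        else:
            p = w @ p
        total = p.sum()
        if total <= 0 or not np.isfinite(total):
            raise FloatingPointError("population mass vanished or diverged")
        p /= total
    return p


def run_ensemble(
    net: ClusteredNetwork, config: Optional[DynamicsConfig] = None, seed=None
) -> ObservationMatrix:
    """Stack final population vectors from independently perturbed runs.

    Each run draws a fresh selection perturbation (a random half of the nodes
    slowed by perturb_size) and a fresh random initial vector.  All runs are
    advanced together: the per-run column scalings (perturbation and
    iteration noise) commute with a single dense matrix product per step.
    """
    config = config or DynamicsConfig()
    rng = as_generator(seed if seed is not None else config.seed)
    n, runs = net.n_nodes, config.runs
    k = int(np.floor(config.perturb_fraction * n))
    pert = np.ones((n, runs))
    for r in range(runs):
        chosen = rng.choice(n, size=k, replace=False)
        pert[chosen, r] = 1.0 - config.perturb_size
    pop = rng.random((n, runs))
    pop /= pop.sum(axis=0, keepdims=True)
    w = net.weights
    a = config.noise_amplitude
    for _ in range(config.iterations):
        scale = pert
        if a > 0:
            scale = pert * (1.0 + rng.uniform(-a, a, size=(n, runs)))
        pop = w @ (scale * pop)
        pop /= pop.sum(axis=0, keepdims=True)
    labels = [f"node{i}" for i in range(n)]
    return ObservationMatrix(pop.T.copy(), feature_labels=labels)
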