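"""Experiment orchestration: detection sweeps and confidence-region scans.

A detection sweep generates data with a known true state count over a grid
of a single swept parameter and records detected vs. true (perfect
detection is the line y = x).  A confidence-region scan locates, for each
(n_rows, n_features) cell, the largest true state count the metric still
resolves to within a relative-error threshold — the data-/feature-limited
operating boundary of the metric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import gard as _gard
from . import network as _network
from . import species as _species
from .metric import MetricConfig, count_heritable_states
from .rng import spawn

__all__ = ["ExperimentSpec", "run_detection_sweep", "run_confidence_region"]


@dataclass
class ExperimentSpec:
    """A sweep specification.

    system : "species", "network" or "gard" — which simulator generates the
        data (the swept parameter and all ``system_params`` are passed to it).
    sweep_param : name of the simulator parameter being swept.
    sweep_values : the grid.
    replicates : independent repetitions per grid value.
    """

    system: str
    sweep_param: str
    sweep_values: Sequence
    system_params: dict = field(default_factory=dict)
    metric: MetricConfig = field(default_factory=MetricConfig)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in {"species", "network", "gard"}:
            raise ValueError(f"unknown system {self.system!r}")
        if len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _generate(system: str, params: dict, rng) -> tuple:
    """Build one observation matrix; returns (matrix, true_count_or_nan)."""
    if system == "species":
        config = _species.SpeciesConfig(**params)
        species_set = _species.make_species_set(config, seed=rng)
        matrix = _species.sample_population(species_set, config, seed=rng)
        return matrix, config.n_species
    if system == "network":
        params = dict(params)
        dyn_keys = {f.name for f in dataclasses.fields(_network.DynamicsConfig)} - {"seed"}
        dyn = _network.DynamicsConfig(**{k: params.pop(k) for k in list(params) if k in dyn_keys})
        net = _network.build_network(**params, seed=rng)
        matrix = _network.run_ensemble(net, dyn, seed=rng)
        return matrix, params["n_clusters"]
    if system == "gard":
        params = dict(params)
        n_pressures = params.pop("n_pressures")
        beta_law = params.pop("beta_law", _gard.DEFAULT_BETA_LAW)
        config = _gard.GardConfig(beta_law=beta_law, **params)
        beta = _gard.generate_beta(config.n_lipid_types, config.beta_law, seed=rng)
        matrix = _gard.gard_observation_matrix(beta, config, n_pressures, seed=rng)
        return matrix, float("nan")
    raise ValueError(f"unknown system {system!r}")


def run_detection_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Detected vs. true count over the sweep grid; deterministic given seed."""
    rngs = spawn(spec.seed, len(spec.sweep_values) * spec.replicates)
    records = []
    k = 0
    for value in spec.sweep_values:
        for rep in range(spec.replicates):
            rng = rngs[k]
            k += 1
            params = dict(spec.system_params)
            params[spec.sweep_param] = value
            matrix, truth = _generate(spec.system, params, rng)
            result = count_heritable_states(matrix, spec.metric, seed=rng)
            records.append(
                (value, rep, truth, result.n_states, result.converged)
            )
    return pd.DataFrame(
        records,
        columns=["sweep_value", "replicate", "true_states", "detected", "converged"],
    )


def run_confidence_region(
    n_rows_grid: Sequence[int],
    n_features_grid: Sequence[int],
    n_species_grid: Sequence[int],
    system_params: Optional[dict] = None,
    metric: Optional[MetricConfig] = None,
    error_threshold: float = 0.5,
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """50%-error boundary of species detection over an (N_P, N_f) grid.

    For each grid cell the true species count is scanned upward; the
    boundary is the last scan point of the initial run whose median (over
    replicates) relative error |detected - true| / true stays below
    ``error_threshold``.  Returns one row per cell with the boundary (0 when
    even the smallest scanned count fails).
    """
    if len(n_rows_grid) == 0 or len(n_features_grid) == 0 or len(n_species_grid) == 0:
        raise ValueError("grids must be nonempty")
    system_params = dict(system_params or {})
    metric = metric or MetricConfig()
    cells = [(int(p), int(f)) for p in n_rows_grid for f in n_features_grid]
    rngs = spawn(seed, len(cells))
    records = []
    for (n_rows, n_features), rng in zip(cells, rngs):
        boundary = 0
        for n_species in n_species_grid:
            errors = []
            for _ in range(replicates):
                params = dict(
                    system_params,
                    n_species=int(n_species),
                    n_rows=n_rows,
                    n_features=n_features,
                )
                matrix, truth = _generate("species", params, rng)
                result = count_heritable_states(matrix, metric, seed=rng)
                errors.append(abs(result.n_states - truth) / truth)
            if float(np.median(errors)) < error_threshold:
                boundary = int(n_species)
            else:
                break
        records.append((n_rows, n_features, boundary))
    return pd.DataFrame(records, columns=["n_rows", "n_features", "boundary"])
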