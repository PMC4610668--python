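"""Model/Results interface to the heritable-state metric.

``HeredityModel`` wraps an observation matrix plus the metric configuration;
``fit()`` runs the regularize → center → PCA → gap-detection pipeline and
returns a ``HeredityResults`` carrying the count, the eigenvalue spectrum,
the full threshold trace, and diagnostics.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metric as _metric
from .data import ObservationMatrix, read_matrix
from .metric import GapResult, MetricConfig

__all__ = ["HeredityModel", "HeredityResults"]


class HeredityModel:
    """Estimate the number of heritable states from end-state observations.

    Parameters
    ----------
    data : ObservationMatrix, DataFrame or 2-d array
        Rows are final system states, one per selection pressure; columns are
        features.
    alpha : float
        Gap-detection sensitivity in (0, 1); 0.1 recommended.
    regularization_copies : int
        Duplicate rows appended as an artificial zero-variance species
        (subtract-one applied to the final count); 0 disables.
    normalize_columns : bool
        Rescale non-constant columns to unit variance before the PCA.
    seed : int, optional
        Seeds the regularization row choice (and subsampling, if used).

    Examples
    --------
    >>> model = HeredityModel(observations, alpha=0.1, seed=0)
    >>> results = model.fit()
    >>> results.n_states
    """

    def __init__(
        self,
        data,
        alpha: float = 0.1,
        regularization_copies: int = 10,
        normalize_columns: bool = False,
        max_iterations: int = 100,
        seed: Optional[int] = None,
    ):
        if isinstance(data, ObservationMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ObservationMatrix.from_dataframe(data)
        else:
            self.data = ObservationMatrix(np.asarray(data, dtype=float))
        self.config = MetricConfig(
            alpha=alpha,
            regularization_copies=regularization_copies,
            normalize_columns=normalize_columns,
            max_iterations=max_iterations,
            seed=seed,
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "HeredityModel":
        return cls(frame, **kwargs)

    @classmethod
    def from_csv(cls, path, delimiter: Optional[str] = None, **kwargs) -> "HeredityModel":
        return cls(read_matrix(path, delimiter=delimiter), **kwargs)

    def fit(self, seed: Optional[int] = None) -> "HeredityResults":
        result = _metric.count_heritable_states(self.data, self.config, seed=seed)
        return HeredityResults(self, result)

    def convergence_curve(
        self,
        row_counts: Sequence[int],
        mode: str = "prefix",
        seed: Optional[int] = None,
    ) -> pd.DataFrame:
        """Detected count vs. number of rows used (see metric.convergence_curve)."""
        return _metric.convergence_curve(
            self.data, self.config, row_counts, mode=mode, seed=seed
        )


class HeredityResults:
    """Fitted results: the heritable-state count and its diagnostics.

    Attributes
    ----------
    n_states : int
        Final estimate (regularization subtract-one and dimension cap applied).
    n_states_raw : int
        ``j + 1`` before corrections.
    j : int
        Number of eigenvalues above the converged threshold.
    spectrum : EigenSpectrum
        Descending PCA eigenvalues of the analysed (augmented) matrix.
    trace : DataFrame
        Per-iteration (j, lambda_gt, T) of the gap search.
    converged : bool
    warnings : list of str
    """

    def __init__(self, model: HeredityModel, result: GapResult):
        self.model = model
        self._result = result
        self.n_states = result.n_states
        self.n_states_raw = result.n_states_raw
        self.j = result.j
        self.alpha = result.alpha
        self.converged = result.converged
        self.gapless = result.gapless
        self.spectrum = result.spectrum
        self.warnings = list(result.warnings)

    @property
    def trace(self) -> pd.DataFrame:
        return self._result.trace_frame()

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "n_states_raw": int(self.n_states_raw),
            "j": int(self.j),
            "alpha": float(self.alpha),
            "converged": bool(self.converged),
            "gapless": bool(self.gapless),
            "trace": [
                {"j": int(j), "lambda_gt": float(lg), "T": float(t)}
                for j, lg, t in self._result.threshold_trace
            ],
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text + "\n")
        return text

    def summary(self) -> str:
        data = self.model.data
        cfg = self.model.config
        lam = self.spectrum.eigenvalues if self.spectrum is not None else np.array([])
        lines = [
            "Heritable-state count (PCA eigenvalue gap)",
            "=" * 48,
            f"{'Observations (rows)':32s}{data.n_rows:>12d}",
            f"{'Features (columns)':32s}{data.n_features:>12d}",
            f"{'alpha':32s}{cfg.alpha:>12.3g}",
            f"{'Regularization copies':32s}{cfg.regularization_copies:>12d}",
            f"{'Converged':32s}{str(self.converged):>12s}",
            "-" * 48,
            f"{'Eigenvalues above threshold (j)':32s}{self.j:>12d}",
            f"{'Raw state count (j + 1)':32s}{self.n_states_raw:>12d}",
            f"{'Heritable states (N_S)':32s}{self.n_states:>12d}",
        ]
        if lam.size:
            top = ", ".join(f"{v:.4g}" for v in lam[: min(5, lam.size)])
            lines.append(f"{'Leading eigenvalues':32s}  [{top}{', ...' if lam.size > 5 else ''}]")
        for w in self.warnings:
            lines.append(f"Warning: {w}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<HeredityResults n_states={self.n_states} converged={self.converged}>"
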