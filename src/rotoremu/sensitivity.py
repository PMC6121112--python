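"""Mean-effect (main-effect) global sensitivity curves through the emulator.

The mean effect of parameter theta_i on output y is the Monte-Carlo average

    ybar(theta_i) ~= (1/N) sum_j Y(lambda_j, theta_i)

where each lambda_j is a joint draw of all other parameters from their
(uniform) variability distributions, taken here from one Latin hypercube so
coverage is even.  The same lambda set is reused across the theta_i grid and
across parameters, which removes Monte-Carlo noise from curve differences of
non-interacting parameters.  For nullable outputs, the average runs over
only the samples the emulator predicts non-null, and the per-grid-value
support count is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .design import ParameterSpace

__all__ = ["MeanEffectCurve", "mean_effect", "base_lambda_sample"]


@dataclass
class MeanEffectCurve:
    """One parameter's mean-effect curve for one output."""

    parameter: str
    output: str
    grid: np.ndarray        # strictly increasing, physical units
    effect: np.ndarray      # NaN where no non-null support
    n_nonnull: np.ndarray   # contributing samples per grid value
    N: int
    seed: int
    n_evaluations: int      # emulator evaluations actually performed


def base_lambda_sample(space: ParameterSpace, N: int, seed: int) -> np.ndarray:
    """One N-point LHS over the full space, shared by all curves."""
    sampler = qmc.LatinHypercube(d=space.dims, seed=seed)
    return space.denormalize(sampler.random(N))


def mean_effect(em, space: ParameterSpace, param_index: int,
                n_grid: int = 100, N: int = 100_000, seed: int = 0,
                output: str | None = None,
                base_sample: np.ndarray | None = None) -> MeanEffectCurve:
    """Mean-effect curve of one parameter.

    ``em`` is either a vectorized callable ``em(X) -> values`` (NaN marking
    null predictions) or a :class:`~rotoremu.emulator.PartitionedEmulator`,
    in which case ``output`` names the biomarker to average.

    ``base_sample`` lets callers share a single lambda set across curves
    (drawn internally from ``seed`` otherwise); the column of the varied
    parameter is overwritten by each grid value in turn.
    """
    if not 0 <= param_index < space.dims:
        raise ValueError("param_index out of range for the parameter space")
    lam = base_lambda_sample(space, N, seed) if base_sample is None \
        else np.array(base_sample, float)
    if lam.shape != (N, space.dims):
        raise ValueError("base_sample shape must be (N, dims)")
    grid = np.linspace(space.low[param_index], space.high[param_index],
                       n_grid)
    if callable(em):
        def _eval(X):
            return np.asarray(em(X), float)
    else:
        if output is None:
            raise ValueError("output biomarker name required for a "
                             "partitioned emulator")

        def _eval(X):
            vals, _ = em.predict_biomarker(X, output)
            return vals

    effect = np.full(n_grid, np.nan)
    n_nonnull = np.zeros(n_grid, dtype=int)
    n_evaluations = 0
    X = lam.copy()
    for g, theta_i in enumerate(grid):
        X[:, param_index] = theta_i
        y = _eval(X)
        n_evaluations += len(X)
        ok = np.isfinite(y)
        n_nonnull[g] = int(ok.sum())
        if n_nonnull[g]:
            effect[g] = float(y[ok].mean())
    return MeanEffectCurve(parameter=space.names[param_index],
                           output=output or "y", grid=grid, effect=effect,
                           n_nonnull=n_nonnull, N=N, seed=seed,
                           n_evaluations=n_evaluations)
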