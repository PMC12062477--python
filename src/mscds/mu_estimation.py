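"""Least-squares estimation of the maximum specific growth rate.

Each sample's cell-count time series is fitted individually: the residual
sum of squares between measured whole-area counts and model-predicted
counts ``N(t) = S * X(t)`` is minimised over ``mu_m`` alone, with the other
model inputs (alpha, epsilon, X_m) fixed at the means of the measured
per-sample values and ``K_s`` at its literature constant.  The per-sample
optima are then aggregated to a mean and sample standard deviation, which
feed the prediction interval.

Model fit quality is scored per seeding-density group with the normalised
root-mean-square error (NRMSE, percent of the group's measured range); a
group passes validation when its NRMSE is below a prior 10% threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .growth_model import DAY1_HOURS, DEFAULT_KS, logistic_density
from .tile_metrics import SampleParameters, TiledObservation, extract_parameters

__all__ = [
    "SampleFit",
    "EstimationResult",
    "residual_sum_of_squares",
    "predict_counts",
    "fit_sample",
    "aggregate",
    "estimate_mu",
    "nrmse",
    "validate_model",
    "NRMSE_THRESHOLD_PERCENT",
]

logger = logging.getLogger(__name__)

NRMSE_THRESHOLD_PERCENT = 10.0
DEFAULT_INIT_MU = 0.03  # h^-1, order of literature values; objective is unimodal


@dataclass(frozen=True)
class SampleFit:
    sample_id: str
    mu_m_hat: float
    rss: float
    n_measure: int
    converged: bool = True


@dataclass(frozen=True)
class EstimationResult:
    """Aggregated growth-rate estimate: mean, sample SD and sample count."""

    mu_m_mean: float
    s: float
    n: int
    fits: tuple = ()


def residual_sum_of_squares(measured, predicted) -> float:
    """RSS = sum_j (N^exp_j - N_j)^2 over paired count vectors."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have equal length")
    if measured.size == 0:
        raise ValueError("need at least one measurement")
    return float(np.sum((measured - predicted) ** 2))


def predict_counts(
    times,
    X_seed: float,
    S: float,
    mu_m: float,
    alpha: float,
    epsilon: float,
    X_m: float,
    K_s: float = DEFAULT_KS,
) -> np.ndarray:
    """Model-predicted whole-area counts N(t) = S * X(t) on ``times`` (h)."""
    dt = np.asarray(times, dtype=float) - DAY1_HOURS
    r = mu_m * (1.0 - epsilon * K_s)
    return S * logistic_density(alpha * X_seed, X_m, r, dt)


def fit_sample(
    obs: TiledObservation,
    alpha: float,
    epsilon: float,
    X_m: float,
    K_s: float = DEFAULT_KS,
    init_mu: float = DEFAULT_INIT_MU,
    max_iter: int = 5000,
    f_tol: float = 1e-10,
) -> SampleFit:
    """Fit mu_m for one sample by Nelder-Mead minimisation of the RSS.

    All observations from Day 1 onward enter the objective (the model is
    undefined earlier).  mu_m is unconstrained in sign; a negative optimum
    or a non-converged simplex is logged but kept, never raised.
    """
    start = obs.day1_index
    times = obs.times[start:]
    measured = obs.totals[start:].astype(float)
    if times.size < 3:
        raise ValueError(
            f"sample {obs.sample_id!r}: need >= 3 timepoints from Day 1 onward"
        )

    def objective(mu_vec: np.ndarray) -> float:
        pred = predict_counts(
            times, obs.X_seed, obs.S, float(mu_vec[0]), alpha, epsilon, X_m, K_s
        )
        return float(np.sum((measured - pred) ** 2))

    # f_tol is relative to the objective scale: an absolute 1e-10 would sit
    # below double-precision noise for count-scale RSS values.
    fatol = f_tol * max(1.0, objective(np.array([init_mu])))
    res = minimize(
        objective,
        x0=[init_mu],
        method="Nelder-Mead",
        options={"maxiter": max_iter, "fatol": fatol, "xatol": 1e-10},
    )
    if not res.success:
        logger.warning(
            "mu_m fit for sample %r did not converge: %s", obs.sample_id, res.message
        )
    mu_hat = float(res.x[0])
    if mu_hat < 0:
        logger.warning("sample %r: fitted mu_m is negative (%.3g)", obs.sample_id, mu_hat)
    return SampleFit(
        sample_id=obs.sample_id,
        mu_m_hat=mu_hat,
        rss=float(res.fun),
        n_measure=int(times.size),
        converged=bool(res.success),
    )


def aggregate(fits: Sequence[SampleFit]) -> EstimationResult:
    """Mean and sample (n-1) standard deviation of the per-sample mu_m."""
    if len(fits) < 2:
        raise ValueError("need at least 2 sample fits to aggregate")
    mus = np.array([f.mu_m_hat for f in fits], dtype=float)
    return EstimationResult(
        mu_m_mean=float(mus.mean()),
        s=float(mus.std(ddof=1)),
        n=len(fits),
        fits=tuple(fits),
    )


def estimate_mu(
    observations: Sequence[TiledObservation],
    K_s: float = DEFAULT_KS,
    init_mu: float = DEFAULT_INIT_MU,
    per_sample_params: bool = False,
    per_density_means: bool = False,
) -> tuple[EstimationResult, list[SampleParameters]]:
    """Full estimation stage: measure (alpha, epsilon, X_m), fit, aggregate.

    By default each sample is fitted with the *global* means of the
    measured parameters.  ``per_density_means`` switches to means within
    each seeding-density group; ``per_sample_params`` uses each sample's
    own measurements (sensitivity mode).
    """
    params = [extract_parameters(o) for o in observations]
    fits = []
    if per_sample_params:
        fixed = {o.sample_id: (p.alpha, p.epsilon, p.X_m) for o, p in zip(observations, params)}
        for obs in observations:
            a, e, xm = fixed[obs.sample_id]
            fits.append(fit_sample(obs, a, e, xm, K_s=K_s, init_mu=init_mu))
    else:
        def _means(idx: Iterable[int]) -> tuple[float, float, float]:
            sel = [params[i] for i in idx]
            return (
                float(np.mean([p.alpha for p in sel])),
                float(np.mean([p.epsilon for p in sel])),
                float(np.mean([p.X_m for p in sel])),
            )

        if per_density_means:
            densities = {o.X_seed for o in observations}
            means_by_density = {
                d: _means([i for i, o in enumerate(observations) if o.X_seed == d])
                for d in densities
            }
            for obs in observations:
                a, e, xm = means_by_density[obs.X_seed]
                fits.append(fit_sample(obs, a, e, xm, K_s=K_s, init_mu=init_mu))
        else:
            a, e, xm = _means(range(len(observations)))
            for obs in observations:
                fits.append(fit_sample(obs, a, e, xm, K_s=K_s, init_mu=init_mu))
    return aggregate(fits), params


def nrmse(measured_by_sample: Sequence, predicted) -> float:
    """NRMSE (percent) of a seeding-density group.

    RMSE over all samples and shared timepoints, normalised by the range
    (max - min) of *all* measured counts in the group.
    """
    measured = np.asarray([np.asarray(m, dtype=float) for m in measured_by_sample])
    predicted = np.asarray(predicted, dtype=float)
    if measured.ndim != 2 or measured.shape[1] != predicted.size:
        raise ValueError("all samples must share the prediction timepoints")
    rng = measured.max() - measured.min()
    if rng <= 0:
        raise ValueError("NRMSE normalisation undefined: zero measured range")
    rmse = np.sqrt(np.mean((measured - predicted[None, :]) ** 2))
    return float(100.0 * rmse / rng)


def validate_model(
    groups: Mapping,
    threshold: float = NRMSE_THRESHOLD_PERCENT,
) -> tuple[bool, dict]:
    """Pass/fail the 10% NRMSE rule for every seeding-density group.

    ``groups`` maps a group key (seeding density) to a pair
    ``(measured_by_sample, predicted)``.  Returns overall pass and a per
    group dict of ``(nrmse_percent, passed)``.
    """
    report = {}
    for key, (measured_by_sample, predicted) in groups.items():
        e = nrmse(measured_by_sample, predicted)
        report[key] = (e, e < threshold)
    ok = all(passed for _, passed in report.values())
    if not ok:
        failing = [k for k, (_, passed) in report.items() if not passed]
        logger.warning("model validation failed for groups: %s", failing)
    return ok, report
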