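"""Dynamic and stochastic simulation of upper/lower growth limits.

Cultivation variability beyond the growth rate itself — adhesion ratio
(cell level), seeding heterogeneity (operation level) and saturation
density (cell level) — is propagated by resampling (alpha, epsilon, X_m)
triples from the empirical per-sample measurements and integrating the
growth model once with mu_m^UP and once with mu_m^LO for every draw.
Because X(t) is monotone in mu_m, the two trajectories bracket the growth
prediction for that parameter draw.

Monte-Carlo convergence is diagnosed on the final (Day-9) cell number via
the batch-means estimate of the relative standard deviation of its mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .growth_model import DAY1_HOURS, DEFAULT_KS, logistic_density, simulate_growth, KineticParameters
from .prediction_interval import PredictionInterval
from .tile_metrics import SampleParameters  # noqa: F401  (re-exported pool input)

__all__ = [
    "ParameterPool",
    "ThetaMatrix",
    "LimitTrajectories",
    "sample_theta",
    "simulate_limits",
    "convergence_diagnostic",
    "CONVERGENCE_THRESHOLD_PERCENT",
]

logger = logging.getLogger(__name__)

#: Warn when the convergence diagnostic exceeds this (percent).
CONVERGENCE_THRESHOLD_PERCENT = 0.2


@dataclass(frozen=True)
class ParameterPool:
    """Empirical per-sample measurements of (alpha, epsilon, X_m)."""

    alphas: np.ndarray
    epsilons: np.ndarray
    X_ms: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alphas", "epsilons", "X_ms"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"parameter pool column {name!r} must be nonempty 1-D")
            object.__setattr__(self, name, arr)
        if np.any(self.alphas <= 0) or np.any(self.epsilons < 0) or np.any(self.X_ms <= 0):
            raise ValueError("pool values violate parameter invariants")

    @classmethod
    def from_samples(cls, samples: Iterable[SampleParameters]) -> "ParameterPool":
        samples = list(samples)
        return cls(
            alphas=np.array([p.alpha for p in samples]),
            epsilons=np.array([p.epsilon for p in samples]),
            X_ms=np.array([p.X_m for p in samples]),
        )


@dataclass(frozen=True)
class ThetaMatrix:
    """M resampled (alpha, epsilon, X_m) rows plus sampling metadata."""

    alpha: np.ndarray
    epsilon: np.ndarray
    X_m: np.ndarray
    seed: int | None
    mode: str

    @property
    def M(self) -> int:
        return self.alpha.size


@dataclass(frozen=True)
class LimitTrajectories:
    """Upper/lower predicted density per Monte-Carlo draw and time."""

    t_grid: np.ndarray  #: hours since seeding
    X_up: np.ndarray  #: (M, n_times) cells cm^-2 at mu_m^UP
    X_lo: np.ndarray  #: (M, n_times) cells cm^-2 at mu_m^LO
    X_seed: float
    theta: ThetaMatrix


def sample_theta(
    pool: ParameterPool,
    M: int,
    seed: int | None = None,
    mode: str = "independent",
    rng: np.random.Generator | None = None,
) -> ThetaMatrix:
    """Draw M parameter triples from the pool with replacement.

    ``independent`` draws each column on its own (each parameter an
    independent random choice); ``joint`` keeps whole per-sample triples
    and thus preserves within-sample correlations.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode == "independent":
        alpha = rng.choice(pool.alphas, size=M, replace=True)
        epsilon = rng.choice(pool.epsilons, size=M, replace=True)
        X_m = rng.choice(pool.X_ms, size=M, replace=True)
    elif mode == "joint":
        if not pool.alphas.size == pool.epsilons.size == pool.X_ms.size:
            raise ValueError("joint sampling requires equal-length pool columns")
        idx = rng.integers(0, pool.alphas.size, size=M)
        alpha = pool.alphas[idx]
        epsilon = pool.epsilons[idx]
        X_m = pool.X_ms[idx]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return ThetaMatrix(alpha=alpha, epsilon=epsilon, X_m=X_m, seed=seed, mode=mode)


def simulate_limits(
    X_seed: float,
    theta: ThetaMatrix,
    pi_bounds: PredictionInterval,
    t_grid,
    K_s: float = DEFAULT_KS,
    method: str = "closed_form",
) -> LimitTrajectories:
    """Upper and lower growth-limit trajectories for every theta row.

    Each row is integrated twice, substituting mu_m^UP and mu_m^LO for the
    growth rate.  The default evaluates the model's closed-form solution
    (vectorised over rows and times); ``method="ode"`` runs the numerical
    integrator row by row, which is equivalent within solver tolerance and
    exists as a cross-check.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < DAY1_HOURS - 1e-9):
        raise ValueError("t_grid must start at or after Day 1 (24 h)")
    X0 = theta.alpha * X_seed  # (M,)
    penalty = 1.0 - theta.epsilon * K_s

    if method == "closed_form":
        dt = (t - DAY1_HOURS)[None, :]
        X_up = logistic_density(
            X0[:, None], theta.X_m[:, None], (pi_bounds.upper * penalty)[:, None], dt
        )
        X_lo = logistic_density(
            X0[:, None], theta.X_m[:, None], (pi_bounds.lower * penalty)[:, None], dt
        )
    elif method == "ode":
        X_up = np.empty((theta.M, t.size))
        X_lo = np.empty((theta.M, t.size))
        for i in range(theta.M):
            for mu, out in ((pi_bounds.upper, X_up), (pi_bounds.lower, X_lo)):
                params = KineticParameters(
                    mu_m=mu,
                    alpha=min(theta.alpha[i], 1.0),
                    epsilon=theta.epsilon[i],
                    X_m=theta.X_m[i],
                    X_seed=X_seed * theta.alpha[i] / min(theta.alpha[i], 1.0),
                    K_s=K_s,
                )
                out[i] = simulate_growth(params, t).densities
    else:
        raise ValueError(f"unknown method {method!r}")
    return LimitTrajectories(t_grid=t, X_up=X_up, X_lo=X_lo, X_seed=X_seed, theta=theta)


def convergence_diagnostic(
    final_counts_per_iteration: Sequence[float], n_batches: int = 10
) -> float:
    """Relative standard deviation (%) of the mean final cell number.

    Batch-means estimator: the M per-iteration final counts are split into
    ``n_batches`` consecutive batches; the standard deviation of the batch
    means divided by sqrt(n_batches) estimates the standard error of the
    overall Monte-Carlo mean, reported relative to that mean in percent.
    """
    x = np.asarray(final_counts_per_iteration, dtype=float)
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if x.size < n_batches:
        raise ValueError(
            f"need at least {n_batches} iterations for {n_batches} batches"
        )
    usable = x.size - (x.size % n_batches)
    batches = x[:usable].reshape(n_batches, -1)
    grand_mean = x.mean()
    if grand_mean == 0:
        raise ValueError("convergence diagnostic undefined for zero mean")
    rsd = 100.0 * batches.mean(axis=1).std(ddof=1) / (np.sqrt(n_batches) * abs(grand_mean))
    if rsd > CONVERGENCE_THRESHOLD_PERCENT:
        logger.warning(
            "Monte-Carlo convergence diagnostic %.3g%% exceeds %.3g%%",
            rsd,
            CONVERGENCE_THRESHOLD_PERCENT,
        )
    return float(rsd)
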