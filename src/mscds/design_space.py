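"""Probabilistic design-space determination over seeding density x harvest time.

The critical process parameters are the seeding density ``X_seed`` and
harvesting time ``t_h``; the critical quality attributes are the harvested
cell number ``N = S * X`` and the confluency ``P = X / X_m``.  A condition
meets the quality specification A when ``N >= N_min`` (inclusive) and
``P < P_max`` (exclusive).

For each grid condition a Monte-Carlo probability is computed from the
upper/lower growth limits: a draw counts as a success only when *both*
limit predictions satisfy A (``with_interval`` mode).  The reference mode
(``point_estimate``) uses the single mean-growth-rate trajectory per draw,
which is the interval-free probability of earlier design-space work.  The
design space is the set of conditions whose probability is at least the
minimum acceptable risk pi (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_model import DAY1_HOURS, DEFAULT_KS, logistic_density
from .prediction_interval import PredictionInterval
from .stochastic_simulation import ParameterPool, ThetaMatrix, sample_theta
from .tile_metrics import DEFAULT_AREA_CM2

__all__ = [
    "QualitySpecification",
    "ConditionGrid",
    "ProbabilityMap",
    "DesignSpace",
    "satisfies_spec",
    "probability_map",
    "determine_design_space",
]


@dataclass(frozen=True)
class QualitySpecification:
    """Quality specification A: N_min <= N (inclusive) and P < P_max (exclusive)."""

    N_min: float = 5.0e4
    P_max: float = 0.8

    def __post_init__(self) -> None:
        if not self.N_min > 0:
            raise ValueError("N_min must be > 0")
        if not 0 < self.P_max <= 1:
            raise ValueError("P_max must be in (0, 1]")


@dataclass(frozen=True)
class ConditionGrid:
    """The (X_seed, t_h) condition lattice explored for the design space."""

    X_seed_values: np.ndarray
    t_h_days: np.ndarray
    S: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "X_seed_values", np.asarray(self.X_seed_values, dtype=float)
        )
        object.__setattr__(self, "t_h_days", np.asarray(self.t_h_days, dtype=float))
        if np.any(self.t_h_days * 24.0 < DAY1_HOURS - 1e-9):
            raise ValueError("harvest times must be Day 1 or later")

    @classmethod
    def default(cls, S: float = DEFAULT_AREA_CM2) -> "ConditionGrid":
        """Design grid: 1500-4500 cells/cm2 step 375, Day 1-9 every 6 h
        (9 x 33 = 297 conditions)."""
        return cls(
            X_seed_values=np.arange(1500.0, 4500.0 + 1.0, 375.0),
            t_h_days=np.linspace(1.0, 9.0, 33),
            S=S,
        )

    @classmethod
    def validation(cls, S: float = DEFAULT_AREA_CM2) -> "ConditionGrid":
        """Validation grid: the three experimental densities over the same
        33 harvest times (99 conditions)."""
        return cls(
            X_seed_values=np.array([1500.0, 3000.0, 4500.0]),
            t_h_days=np.linspace(1.0, 9.0, 33),
            S=S,
        )

    @property
    def t_hours(self) -> np.ndarray:
        return self.t_h_days * 24.0

    @property
    def n_conditions(self) -> int:
        return self.X_seed_values.size * self.t_h_days.size


@dataclass(frozen=True)
class ProbabilityMap:
    """h(x, t): percent probability of meeting the specification, per condition."""

    h: np.ndarray  #: (n_X_seed, n_t_h) percent in [0, 100]
    grid: ConditionGrid
    spec: QualitySpecification
    M: int
    mode: str
    seed: int | None
    sampling: str

    def to_frame(self, ds: "DesignSpace | None" = None) -> pd.DataFrame:
        """Tidy export: one row per condition (h at 0.1% resolution)."""
        xs, th = np.meshgrid(self.grid.X_seed_values, self.grid.t_h_days, indexing="ij")
        out = pd.DataFrame(
            {
                "X_seed_cells_per_cm2": xs.ravel(),
                "t_h_days": th.ravel(),
                "h_percent": np.round(self.h, 1).ravel(),
            }
        )
        if ds is not None:
            out["in_DS"] = ds.mask.ravel()
        return out


@dataclass(frozen=True)
class DesignSpace:
    """Conditions whose predicted probability reaches the acceptable risk pi."""

    mask: np.ndarray  #: boolean (n_X_seed, n_t_h), h >= pi
    pi: float
    source: ProbabilityMap

    @property
    def n_conditions(self) -> int:
        return int(self.mask.sum())


def satisfies_spec(N, P, spec: QualitySpecification):
    """Indicator of the quality specification; broadcasts over arrays."""
    N = np.asarray(N, dtype=float)
    P = np.asarray(P, dtype=float)
    out = (N >= spec.N_min) & (P < spec.P_max)
    return bool(out) if out.ndim == 0 else out


def probability_map(
    grid: ConditionGrid,
    pool: ParameterPool,
    pi_bounds: PredictionInterval,
    spec: QualitySpecification = QualitySpecification(),
    M: int = 1000,
    seed: int | None = None,
    mode: str = "with_interval",
    sampling: str = "independent",
    K_s: float = DEFAULT_KS,
    theta: ThetaMatrix | None = None,
) -> ProbabilityMap:
    """Monte-Carlo probability of meeting the specification, per condition.

    One theta matrix is shared across the whole grid, and per (theta row,
    X_seed) a single closed-form trajectory pair is evaluated at all
    harvest times: the probabilities at every t_h come from the same
    simulated trajectories.  The confluency of each draw uses that draw's
    own X_m.
    """
    if mode not in ("with_interval", "point_estimate"):
        raise ValueError(f"unknown probability mode {mode!r}")
    if theta is None:
        theta = sample_theta(pool, M, seed=seed, mode=sampling)
    dt = (grid.t_hours - DAY1_HOURS)[None, :]
    penalty = (1.0 - theta.epsilon * K_s)[:, None]
    X_m = theta.X_m[:, None]

    h = np.empty((grid.X_seed_values.size, grid.t_h_days.size))
    for i, x_seed in enumerate(grid.X_seed_values):
        X0 = (theta.alpha * x_seed)[:, None]
        if mode == "with_interval":
            ok = np.ones((theta.M, grid.t_h_days.size), dtype=bool)
            for mu in (pi_bounds.upper, pi_bounds.lower):
                X = logistic_density(X0, X_m, mu * penalty, dt)
                ok &= satisfies_spec(grid.S * X, X / X_m, spec)
        else:
            X = logistic_density(X0, X_m, pi_bounds.mean * penalty, dt)
            ok = satisfies_spec(grid.S * X, X / X_m, spec)
        h[i] = 100.0 * ok.mean(axis=0)
    return ProbabilityMap(
        h=h, grid=grid, spec=spec, M=theta.M, mode=mode, seed=seed, sampling=sampling
    )


def determine_design_space(pmap: ProbabilityMap, pi: float) -> DesignSpace:
    """Threshold the probability map at the minimum acceptable risk pi.

    Inclusive: a condition with h exactly equal to pi belongs to the DS.
    """
    if not 0 < pi <= 100:
        raise ValueError(f"pi must be in (0, 100], got {pi}")
    return DesignSpace(mask=pmap.h >= pi, pi=float(pi), source=pmap)
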