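"""Two-sided Student-t prediction interval for the maximum specific growth rate.

A prediction interval brackets a *future single observation* — here, the
mu_m of a new cultivation sample — and is wider than the confidence
interval of the mean by the sqrt(1 + 1/n) factor:

    mu_m^UP/LO = mean +/- t(1 - (1-level)/2, n-1) * s * sqrt(1 + 1/n)

with n the number of fitted samples (never the number of timepoints).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .mu_estimation import EstimationResult

__all__ = ["PredictionInterval", "t_quantile", "mu_m_prediction_interval"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionInterval:
    mean: float
    s: float
    n: int
    level: float
    upper: float
    lower: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


def t_quantile(p: float, df: int) -> float:
    """p-quantile of Student's t distribution with ``df`` degrees of freedom."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile probability must be in (0, 1), got {p}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(p, df))


def mu_m_prediction_interval(
    est: EstimationResult, level: float = 0.95
) -> PredictionInterval:
    """Two-sided prediction interval for a fresh sample's mu_m.

    Degrees of freedom are ``n - 1`` with ``n`` the number of fitted
    samples.  A negative lower bound is biologically implausible and is
    logged, but never clipped.
    """
    if est.n < 2:
        raise ValueError("prediction interval requires n >= 2 samples")
    if est.s < 0:
        raise ValueError("sample standard deviation must be >= 0")
    half = (
        t_quantile(1.0 - (1.0 - level) / 2.0, est.n - 1)
        * est.s
        * (1.0 + 1.0 / est.n) ** 0.5
    )
    lower = est.mu_m_mean - half
    if lower < 0:
        logger.warning("lower prediction bound for mu_m is negative (%.3g)", lower)
    return PredictionInterval(
        mean=est.mu_m_mean,
        s=est.s,
        n=est.n,
        level=level,
        upper=est.mu_m_mean + half,
        lower=lower,
    )
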