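"""Design-space validation against held-out cultivation experiments.

For every experimental condition the measurements yield an experimental
probability h_exp: the fraction of validation samples whose (N_exp, P_exp)
meet the quality specification.  Crossing h (predicted) and h_exp at the
acceptable risk pi classifies each condition:

* CDS     — correctly identified feasible   (h >= pi and h_exp >= pi)
* C-notDS — correctly identified infeasible (h < pi and h_exp < pi)
* IDS     — incorrectly identified feasible (h >= pi, h_exp < pi)
* I-notDS — incorrectly identified infeasible (h < pi, h_exp >= pi)

Three summary ratios follow: R1 = nCDS/(nCDS+nIDS), precision-like, how
conservatively the DS proposes feasible conditions; R2 = nCDS/(nCDS+nI-notDS),
recall-like; R3 = nC-notDS/(nC-notDS+nIDS), specificity-like.  A ratio with
zero denominator is reported as missing, never as 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_space import (
    ConditionGrid,
    DesignSpace,
    QualitySpecification,
    determine_design_space,
    probability_map,
    satisfies_spec,
)
from .growth_model import DEFAULT_KS
from .mu_estimation import estimate_mu, predict_counts, validate_model
from .prediction_interval import mu_m_prediction_interval
from .stochastic_simulation import ParameterPool
from .tile_metrics import TiledObservation, max_cell_density

__all__ = [
    "ExperimentalCondition",
    "ConditionCategory",
    "ValidationMetrics",
    "ValidationResult",
    "experimental_probability",
    "categorize",
    "compute_metrics",
    "conditions_from_observations",
    "validate_design_space",
    "permutation_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentalCondition:
    """Validation measurements at one (X_seed, t_h) condition."""

    X_seed: float
    t_h_days: float
    N_exp: np.ndarray  #: measured cell number per sample
    P_exp: np.ndarray  #: measured confluency per sample

    def __post_init__(self) -> None:
        object.__setattr__(self, "N_exp", np.asarray(self.N_exp, dtype=float))
        object.__setattr__(self, "P_exp", np.asarray(self.P_exp, dtype=float))
        if self.N_exp.size == 0 or self.N_exp.shape != self.P_exp.shape:
            raise ValueError("need >= 1 paired (N_exp, P_exp) samples")

    @property
    def n(self) -> int:
        return self.N_exp.size


class ConditionCategory(str, Enum):
    CDS = "CDS"
    C_NOT_DS = "C_notDS"
    IDS = "IDS"
    I_NOT_DS = "I_notDS"


@dataclass(frozen=True)
class ValidationMetrics:
    nCDS: int
    nC_notDS: int
    nIDS: int
    nI_notDS: int
    R1: float | None
    R2: float | None
    R3: float | None


@dataclass(frozen=True)
class ValidationResult:
    table: pd.DataFrame  #: per-condition X_seed, t_h_days, h, h_exp, category
    metrics: ValidationMetrics
    design_space: DesignSpace


def experimental_probability(
    cond: ExperimentalCondition, spec: QualitySpecification
) -> float:
    """Percent of validation samples meeting the specification at this condition."""
    ok = satisfies_spec(cond.N_exp, cond.P_exp, spec)
    return float(100.0 * np.mean(ok))


def categorize(h: float, h_exp: float, pi: float) -> ConditionCategory:
    """Four-way classification by crossing h and h_exp at pi (both inclusive)."""
    predicted = h >= pi
    observed = h_exp >= pi
    if predicted and observed:
        return ConditionCategory.CDS
    if predicted and not observed:
        return ConditionCategory.IDS
    if not predicted and observed:
        return ConditionCategory.I_NOT_DS
    return ConditionCategory.C_NOT_DS


def compute_metrics(categories: Sequence[ConditionCategory]) -> ValidationMetrics:
    """Counts of the four categories and the R1/R2/R3 ratios."""
    if len(categories) == 0:
        raise ValueError("need at least one categorized condition")
    counts = {c: 0 for c in ConditionCategory}
    for c in categories:
        counts[ConditionCategory(c)] += 1

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as missing", name)
            return None
        return num / den

    nCDS = counts[ConditionCategory.CDS]
    nC = counts[ConditionCategory.C_NOT_DS]
    nIDS = counts[ConditionCategory.IDS]
    nI = counts[ConditionCategory.I_NOT_DS]
    return ValidationMetrics(
        nCDS=nCDS,
        nC_notDS=nC,
        nIDS=nIDS,
        nI_notDS=nI,
        R1=ratio(nCDS, nCDS + nIDS, "R1"),
        R2=ratio(nCDS, nCDS + nI, "R2"),
        R3=ratio(nC, nC + nIDS, "R3"),
    )


def conditions_from_observations(
    observations: Sequence[TiledObservation],
    X_m_mode: str = "per_sample",
) -> list[ExperimentalCondition]:
    """Build validation conditions from raw observations.

    Each sample contributes, at every timepoint, its measured cell number
    (whole-area count) and confluency P_exp = N_exp / (S * X_m).  By
    default X_m is each sample's own measured maximum density; with
    ``X_m_mode="global_mean"`` the mean over all samples is used instead.
    """
    if X_m_mode not in ("per_sample", "global_mean"):
        raise ValueError(f"unknown X_m mode {X_m_mode!r}")
    x_ms = {o.sample_id: max_cell_density(o) for o in observations}
    if X_m_mode == "global_mean":
        mean_xm = float(np.mean(list(x_ms.values())))
        x_ms = {k: mean_xm for k in x_ms}

    buckets: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for obs in observations:
        totals = obs.totals
        for j, t in enumerate(obs.times):
            N = float(totals[j])
            P = N / (obs.S * x_ms[obs.sample_id])
            buckets.setdefault((obs.X_seed, t / 24.0), []).append((N, P))
    return [
        ExperimentalCondition(
            X_seed=x, t_h_days=th,
            N_exp=[n for n, _ in vals], P_exp=[p for _, p in vals],
        )
        for (x, th), vals in sorted(buckets.items())
    ]


def _grid_index(grid: ConditionGrid, cond: ExperimentalCondition) -> tuple[int, int]:
    i = np.flatnonzero(np.isclose(grid.X_seed_values, cond.X_seed))
    j = np.flatnonzero(np.isclose(grid.t_h_days, cond.t_h_days))
    if i.size != 1 or j.size != 1:
        raise ValueError(
            f"condition (X_seed={cond.X_seed}, t_h={cond.t_h_days} d) does not "
            "match the probability-map grid exactly"
        )
    return int(i[0]), int(j[0])


def validate_design_space(
    ds: DesignSpace,
    conditions: Sequence[ExperimentalCondition],
    spec: QualitySpecification | None = None,
) -> ValidationResult:
    """Categorise every experimental condition against the DS and score it.

    Conditions are matched to grid cells exactly on (X_seed, t_h); a
    condition outside the grid is an error, never snapped.
    """
    if spec is None:
        spec = ds.source.spec
    rows = []
    categories = []
    for cond in conditions:
        i, j = _grid_index(ds.source.grid, cond)
        h = float(ds.source.h[i, j])
        h_exp = experimental_probability(cond, spec)
        cat = categorize(h, h_exp, ds.pi)
        categories.append(cat)
        rows.append((cond.X_seed, cond.t_h_days, cond.n, h, h_exp, cat.value))
    table = pd.DataFrame(
        rows,
        columns=["X_seed_cells_per_cm2", "t_h_days", "n_samples", "h_percent",
                 "h_exp_percent", "category"],
    )
    return ValidationResult(
        table=table, metrics=compute_metrics(categories), design_space=ds
    )


def permutation_study(
    experiments: Mapping[str, Sequence[TiledObservation]],
    grid: ConditionGrid | None = None,
    pis: Sequence[float] = (50.0, 70.0, 90.0),
    spec: QualitySpecification = QualitySpecification(),
    M: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    sampling: str = "independent",
    K_s: float = DEFAULT_KS,
) -> pd.DataFrame:
    """Rotate the pre-experiment role over labelled experiment groups.

    For every group label the full workflow is re-run with that group as
    the pre-experiment (growth-rate re-estimation, prediction interval,
    parameter pool, probability map) and the pooled remaining groups as
    validation data, for each acceptable risk in ``pis``.  NRMSE-based
    model validation on the held-out groups is reported alongside.

    Returns one row per (pre-experiment, pi) with the interval, DS size,
    NRMSE outcome and R1/R2/R3.
    """
    if len(experiments) < 2:
        raise ValueError("permutation study needs >= 2 labelled experiment groups")
    if grid is None:
        grid = ConditionGrid.default()
    rows = []
    for k, (pre_label, pre_obs) in enumerate(sorted(experiments.items())):
        val_obs = [
            o for label, obs in sorted(experiments.items()) if label != pre_label
            for o in obs
        ]
        est, params = estimate_mu(pre_obs, K_s=K_s)
        bounds = mu_m_prediction_interval(est, level=level)
        pool = ParameterPool.from_samples(params)

        # NRMSE model validation on the held-out groups.
        a = float(np.mean([p.alpha for p in params]))
        e = float(np.mean([p.epsilon for p in params]))
        xm = float(np.mean([p.X_m for p in params]))
        groups = {}
        for density in sorted({o.X_seed for o in val_obs}):
            members = [o for o in val_obs if o.X_seed == density]
            times = members[0].times
            measured = [m.totals.astype(float) for m in members]
            predicted = predict_counts(
                times, density, members[0].S, est.mu_m_mean, a, e, xm, K_s
            )
            groups[density] = (measured, predicted)
        nrmse_ok, nrmse_report = validate_model(groups)

        pmap = probability_map(
            grid, pool, bounds, spec=spec, M=M,
            seed=None if seed is None else seed + k,
            sampling=sampling, K_s=K_s,
        )
        conditions = conditions_from_observations(val_obs)
        for pi in pis:
            ds = determine_design_space(pmap, pi)
            result = validate_design_space(ds, conditions, spec=spec)
            m = result.metrics
            rows.append(
                {
                    "pre_experiment": pre_label,
                    "pi_percent": pi,
                    "mu_m_mean": est.mu_m_mean,
                    "mu_m_s": est.s,
                    "mu_m_upper": bounds.upper,
                    "mu_m_lower": bounds.lower,
                    "nrmse_pass": nrmse_ok,
                    "nrmse_max_percent": max(v for v, _ in nrmse_report.values()),
                    "ds_conditions": ds.n_conditions,
                    "nCDS": m.nCDS,
                    "nC_notDS": m.nC_notDS,
                    "nIDS": m.nIDS,
                    "nI_notDS": m.nI_notDS,
                    "R1": m.R1,
                    "R2": m.R2,
                    "R3": m.R3,
                }
            )
    return pd.DataFrame(rows)
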