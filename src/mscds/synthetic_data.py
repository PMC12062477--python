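"""Synthetic cultivation experiments with the statistical structure the
design-space workflow assumes.

One generated "experiment" mirrors the wet-lab design: three operators,
three seeding densities (1500/3000/4500 cells cm^-2), six replicate wells
each, imaged every 6 h from Day 1 to Day 9 as a 64-tile grid covering a
2.3409 cm^2 restricted culture area.

Per sample the generator draws a true maximum specific growth rate
mu_m ~ Normal(2.76e-2, 1.46e-3) h^-1, an adhesion ratio alpha ~ Beta, and a
saturation density X_m ~ truncated Normal; the adhered Day-1 cells are
allocated to the 64 tiles by a symmetric Dirichlet-multinomial whose
concentration controls the realized seeding heterogeneity epsilon (recorded
as truth, exactly as the analysis later measures it).  The total density is
propagated with the closed-form growth law and observed counts carry
multiplicative lognormal counting noise; densities are capped at X_m.

Tile allocation at later timepoints redraws a multinomial over the
sample's fixed spatial weights with a per-tile capacity of S*X_m/64, so
tiles saturate locally and a confluent well ends near-uniform — the
behaviour the max-tile X_m statistic relies on.  A ``proportional`` mode
that freezes the Day-1 tile fractions is available instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .growth_model import DAY1_HOURS, DEFAULT_KS, logistic_density
from .tile_metrics import (
    DEFAULT_AREA_CM2,
    N_TILES,
    TiledObservation,
    write_observations_csv,
)

__all__ = ["GeneratorConfig", "SyntheticExperiment", "generate_sample", "generate_experiment"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and variability settings for the generator.

    Defaults reproduce the experimental design of the cultivation study
    the package models: densities, replication, operators, imaging
    schedule and the growth-rate distribution are as reported; the
    remaining variability levels are calibrated to realistic adherent
    MSC cultures (see docs/methods.md).
    """

    seeding_densities: tuple = (1500.0, 3000.0, 4500.0)  # cells cm^-2
    replicates: int = 6
    operators: tuple = ("A", "B", "C")
    mu_m_mean: float = 2.76e-2  # h^-1
    mu_m_sd: float = 1.46e-3  # h^-1
    alpha_mean: float = 0.80
    alpha_concentration: float = 200.0  # Beta concentration (a+b)
    dirichlet_concentration: float = 1000.0  # per-tile; larger = more uniform
    X_m_mean: float = 4.0e4  # cells cm^-2
    X_m_sd: float = 5.0e2
    count_noise_cv: float = 0.03
    tile_capacity_cv: float = 0.015  # local saturation-density variation
    noise_model: str = "lognormal"  # or "poisson"
    tile_allocation: str = "resample"  # or "proportional"
    operator_mu_offsets: Mapping[str, float] | None = None
    S: float = DEFAULT_AREA_CM2  # cm^2
    K_s: float = DEFAULT_KS
    time_step_h: float = 6.0
    horizon_days: float = 9.0
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.seeding_densities:
            raise ValueError("need >= 1 replicate and >= 1 seeding density")
        if not 0 < self.alpha_mean < 1 or self.alpha_concentration <= 0:
            raise ValueError("invalid alpha distribution")
        if self.X_m_mean <= 0 or self.X_m_sd < 0 or self.dirichlet_concentration <= 0:
            raise ValueError("invalid X_m / Dirichlet settings")
        if self.count_noise_cv < 0 or self.tile_capacity_cv < 0:
            raise ValueError("noise/capacity CVs must be >= 0")
        if self.noise_model not in ("lognormal", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.tile_allocation not in ("resample", "proportional"):
            raise ValueError(f"unknown tile allocation {self.tile_allocation!r}")
        if self.horizon_days * 24.0 < DAY1_HOURS or self.time_step_h <= 0:
            raise ValueError("time grid must cover Day 1 onward")

    @property
    def times(self) -> np.ndarray:
        """Observation grid in hours since seeding (Day 1 to the horizon)."""
        return np.arange(DAY1_HOURS, self.horizon_days * 24.0 + 1e-9, self.time_step_h)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Generated dataset plus the per-sample ground truth."""

    observations: list
    truth: pd.DataFrame
    config: GeneratorConfig

    def by_operator(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for obs in self.observations:
            out.setdefault(obs.operator, []).append(obs)
        return out

    def write(self, csv_path, truth_path=None) -> None:
        write_observations_csv(self.observations, csv_path)
        if truth_path is not None:
            payload = {
                "seed": self.config.seed,
                "samples": self.truth.to_dict(orient="records"),
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _allocate_tiles(
    total: int, weights: np.ndarray, caps: np.ndarray, rng: np.random.Generator,
    mode: str, day1_fractions: np.ndarray | None = None,
) -> np.ndarray:
    """Distribute ``total`` cells over 64 tiles, tile i holding <= caps[i]."""
    if total > caps.sum():
        raise ValueError("total exceeds tile capacity")
    if mode == "proportional" and day1_fractions is not None:
        counts = np.floor(total * day1_fractions).astype(np.int64)
        remainder = total - counts.sum()
        if remainder > 0:
            order = np.argsort(-(total * day1_fractions - counts))
            counts[order[:remainder]] += 1
    else:
        counts = rng.multinomial(total, weights)
    # Local saturation: clip full tiles and push the excess into the rest.
    for _ in range(200):
        excess = counts - caps
        over = excess > 0
        if not over.any():
            break
        spill = int(excess[over].sum())
        counts = np.minimum(counts, caps)
        room = counts < caps
        w = weights * room
        counts += rng.multinomial(spill, w / w.sum())
    return np.minimum(counts, caps)


def generate_sample(
    cfg: GeneratorConfig,
    X_seed: float,
    rng: np.random.Generator,
    operator: str = "A",
    sample_id: str | None = None,
) -> tuple[TiledObservation, dict]:
    """Generate one cultivated well and its ground-truth record."""
    offset = (cfg.operator_mu_offsets or {}).get(operator, 0.0)
    mu_m = rng.normal(cfg.mu_m_mean + offset, cfg.mu_m_sd)
    a = cfg.alpha_mean * cfg.alpha_concentration
    b = (1.0 - cfg.alpha_mean) * cfg.alpha_concentration
    alpha = float(np.clip(rng.beta(a, b), 1e-6, 1.0))
    X_m = rng.normal(cfg.X_m_mean, cfg.X_m_sd)
    while X_m <= alpha * X_seed or X_m <= 0:  # saturation above the inoculum
        X_m = rng.normal(cfg.X_m_mean, cfg.X_m_sd)

    weights = rng.dirichlet(np.full(N_TILES, cfg.dirichlet_concentration))
    # Local saturation density varies a little from tile to tile, so the
    # densest tile of a confluent well slightly exceeds the well average.
    local = np.maximum(rng.normal(1.0, cfg.tile_capacity_cv, N_TILES), 0.5)
    caps = np.ceil(cfg.S * X_m / N_TILES * local).astype(np.int64)
    n_day1 = int(round(alpha * cfg.S * X_seed))
    day1_tiles = _allocate_tiles(n_day1, weights, caps, rng, "resample")
    day1_fractions = day1_tiles / max(n_day1, 1)

    times = cfg.times
    tile_counts = np.empty((times.size, N_TILES), dtype=np.int64)
    tile_counts[0] = day1_tiles

    # Realized heterogeneity drives the true growth penalty, mirroring how
    # the analysis measures epsilon rather than setting it.
    frac = day1_tiles / max(n_day1, 1)
    epsilon = float(np.sqrt(np.mean((frac - 1.0 / N_TILES) ** 2)))

    X0 = n_day1 / cfg.S
    r = mu_m * (1.0 - epsilon * cfg.K_s)
    X = logistic_density(X0, X_m, r, times - DAY1_HOURS)
    expected = cfg.S * X  # whole-area cell number, noise-free

    max_total = min(int(np.floor(cfg.S * X_m)), int(caps.sum()))
    for j in range(1, times.size):
        if cfg.noise_model == "lognormal":
            if cfg.count_noise_cv > 0:
                sigma = float(np.sqrt(np.log1p(cfg.count_noise_cv**2)))
                factor = rng.lognormal(-0.5 * sigma**2, sigma)
            else:
                factor = 1.0
            total = int(round(expected[j] * factor))
            total = min(max(total, 0), max_total)
            tile_counts[j] = _allocate_tiles(
                total, weights, caps, rng, cfg.tile_allocation, day1_fractions
            )
        else:  # per-tile Poisson counting noise
            lam = np.minimum(expected[j] * weights, caps)
            tiles = np.minimum(rng.poisson(lam), caps)
            tile_counts[j] = tiles

    obs = TiledObservation(
        sample_id=sample_id or f"{operator}-{int(X_seed)}",
        operator=operator,
        X_seed=X_seed,
        S=cfg.S,
        times=times,
        tile_counts=tile_counts,
    )
    truth = {
        "sample_id": obs.sample_id,
        "operator": operator,
        "X_seed": X_seed,
        "mu_m": mu_m,
        "alpha": alpha,
        "alpha_realized": n_day1 / (cfg.S * X_seed),
        "epsilon_realized": epsilon,
        "X_m": X_m,
    }
    return obs, truth


def generate_experiment(cfg: GeneratorConfig) -> SyntheticExperiment:
    """Generate the full operators x densities x replicates design.

    Fully determined by ``cfg.seed``: identical configs produce identical
    datasets (and byte-identical CSV exports).
    """
    rng = np.random.default_rng(cfg.seed)
    observations = []
    truth_rows = []
    for operator in cfg.operators:
        for density in cfg.seeding_densities:
            for rep in range(1, cfg.replicates + 1):
                sid = f"Exp2{operator}-{int(density)}-r{rep}"
                obs, truth = generate_sample(
                    cfg, density, rng, operator=operator, sample_id=sid
                )
                observations.append(obs)
                truth_rows.append(truth)
    return SyntheticExperiment(
        observations=observations, truth=pd.DataFrame(truth_rows), config=cfg
    )
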