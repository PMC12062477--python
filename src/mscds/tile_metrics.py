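"""Per-sample model inputs (alpha, epsilon, X_m) from tiled cell counts.

A cultivated well is imaged as an 8 x 8 tiling (64 images) covering the
restricted culture area; image analysis yields an adhesion-cell count per
tile per timepoint.  Three per-sample quantities feed the growth model:

* adhesion ratio  alpha = (sum of Day-1 tile counts) / (S * X_seed)
* seeding heterogeneity  epsilon = population SD of the normalised Day-1
  tile counts:  sqrt( (1/64) * sum_i (N_i / sum_j N_j - 1/64)^2 )
* maximum cell density  X_m = 64 * max(N^img) / S, the max running over
  all tiles and all timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_model import DAY1_HOURS

__all__ = [
    "N_TILES",
    "DEFAULT_AREA_CM2",
    "CIRCLE_AREA_CM2",
    "DAY1_TOLERANCE_HOURS",
    "TiledObservation",
    "SampleParameters",
    "adhesion_ratio",
    "seeding_heterogeneity",
    "max_cell_density",
    "extract_parameters",
    "read_observations_csv",
    "write_observations_csv",
]

N_TILES = 64

#: Square 15.3 mm x 15.3 mm tiling area (default reading of the imaged area).
DEFAULT_AREA_CM2 = 2.3409
#: Circle of diameter 15.3 mm, the alternative reading; selectable via config.
CIRCLE_AREA_CM2 = float(np.pi * (1.53 / 2.0) ** 2)

#: The "Day 1" observation must lie within this window around 24 h.
DAY1_TOLERANCE_HOURS = 3.0

CSV_COLUMNS = [
    "sample_id",
    "operator",
    "X_seed_cells_per_cm2",
    "time_h",
    "tile_index",
    "count",
]


@dataclass
class TiledObservation:
    """One cultivated sample: counts per timepoint, optionally per tile."""

    sample_id: str
    operator: str
    X_seed: float
    S: float
    times: np.ndarray
    tile_counts: np.ndarray | None = None
    total_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a nonempty 1-D array of hours")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if self.X_seed <= 0:
            raise ValueError("X_seed must be > 0")
        if self.S <= 0:
            raise ValueError("culture area S must be > 0")
        if self.tile_counts is not None:
            self.tile_counts = np.asarray(self.tile_counts)
            if self.tile_counts.shape != (self.times.size, N_TILES):
                raise ValueError(
                    f"tile_counts must have shape (n_timepoints, {N_TILES}); "
                    f"got {self.tile_counts.shape}"
                )
            if np.any(self.tile_counts < 0):
                raise ValueError("tile counts must be >= 0")
        if self.total_counts is not None:
            self.total_counts = np.asarray(self.total_counts)
            if self.total_counts.shape != self.times.shape:
                raise ValueError("total_counts must match times in length")
            if np.any(self.total_counts < 0):
                raise ValueError("total counts must be >= 0")
        if self.tile_counts is None and self.total_counts is None:
            raise ValueError("observation needs tile_counts or total_counts")

    @property
    def tile_resolved(self) -> bool:
        return self.tile_counts is not None

    @property
    def totals(self) -> np.ndarray:
        """Whole-area adhesion-cell count per timepoint."""
        if self.tile_counts is not None:
            return self.tile_counts.sum(axis=1)
        return self.total_counts

    @property
    def day1_index(self) -> int:
        """Index of the observation closest to 24 h post seeding.

        Raises if no observation falls within +/- 3 h of 24 h.
        """
        i = int(np.argmin(np.abs(self.times - DAY1_HOURS)))
        if abs(self.times[i] - DAY1_HOURS) > DAY1_TOLERANCE_HOURS:
            raise ValueError(
                f"sample {self.sample_id!r}: no observation within "
                f"{DAY1_TOLERANCE_HOURS} h of Day 1 (24 h)"
            )
        return i


@dataclass(frozen=True)
class SampleParameters:
    """Measured (alpha, epsilon, X_m) for one sample."""

    sample_id: str
    alpha: float
    epsilon: float
    X_m: float


def adhesion_ratio(obs: TiledObservation) -> float:
    """Fraction of seeded cells attached on Day 1."""
    seeded = obs.S * obs.X_seed
    if seeded <= 0:
        raise ValueError("S * X_seed must be > 0")
    return float(obs.totals[obs.day1_index]) / seeded


def seeding_heterogeneity(obs: TiledObservation) -> float:
    """Population SD of the normalised Day-1 tile counts.

    Zero for a perfectly uniform seeding; sqrt(63)/64 ~ 0.124 when every
    cell lands in a single tile.  Undefined without tile resolution or
    when no cells attached on Day 1.
    """
    if not obs.tile_resolved:
        raise ValueError(
            "seeding heterogeneity requires tile-resolved counts"
        )
    day1 = obs.tile_counts[obs.day1_index].astype(float)
    total = day1.sum()
    if total <= 0:
        raise ValueError("seeding heterogeneity undefined: Day-1 count is zero")
    frac = day1 / total
    return float(np.sqrt(np.mean((frac - 1.0 / N_TILES) ** 2)))


def max_cell_density(obs: TiledObservation, assume_uniform: bool = False) -> float:
    """Max cell density X_m = 64 * max tile count / S over all timepoints.

    Without tile resolution the statistic is only defined under a tile
    uniformity assumption (``assume_uniform=True``), where it reduces to
    ``max(total) / S``.
    """
    if obs.tile_resolved:
        return N_TILES * float(obs.tile_counts.max()) / obs.S
    if not assume_uniform:
        raise ValueError(
            "max_cell_density needs tile counts; pass assume_uniform=True "
            "to accept the totals-based estimate"
        )
    return float(obs.totals.max()) / obs.S


def extract_parameters(
    obs: TiledObservation,
    assume_uniform: bool = False,
    epsilon: float | None = None,
) -> SampleParameters:
    """Bundle alpha, epsilon and X_m for one sample.

    For totals-only observations pass ``assume_uniform=True`` and supply
    ``epsilon`` externally (the tile formula is undefined on totals).
    """
    if obs.tile_resolved:
        eps = seeding_heterogeneity(obs) if epsilon is None else epsilon
    else:
        if not assume_uniform or epsilon is None:
            raise ValueError(
                "totals-only observations require assume_uniform=True and an "
                "externally supplied epsilon"
            )
        eps = epsilon
    return SampleParameters(
        sample_id=obs.sample_id,
        alpha=adhesion_ratio(obs),
        epsilon=eps,
        X_m=max_cell_density(obs, assume_uniform=assume_uniform),
    )


def read_observations_csv(path, S: float = DEFAULT_AREA_CM2) -> list[TiledObservation]:
    """Read the long-format observation CSV.

    Columns: sample_id, operator, X_seed_cells_per_cm2, time_h, tile_index
    (0-63, blank for totals-only rows), count.  Header row required.
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV is missing columns: {sorted(missing)}")

    observations: list[TiledObservation] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        operators = grp["operator"].unique()
        densities = grp["X_seed_cells_per_cm2"].unique()
        if len(operators) != 1 or len(densities) != 1:
            raise ValueError(
                f"sample {sample_id!r} has inconsistent operator/X_seed rows"
            )
        tiled = grp["tile_index"].notna()
        if tiled.all():
            pivot = grp.pivot_table(
                index="time_h", columns="tile_index", values="count", aggfunc="sum"
            ).sort_index()
            if pivot.shape[1] != N_TILES or pivot.isna().any().any():
                raise ValueError(
                    f"sample {sample_id!r}: tile-resolved data must cover all "
                    f"{N_TILES} tiles at every timepoint"
                )
            obs = TiledObservation(
                sample_id=str(sample_id),
                operator=str(operators[0]),
                X_seed=float(densities[0]),
                S=S,
                times=pivot.index.to_numpy(dtype=float),
                tile_counts=pivot.to_numpy(dtype=np.int64),
            )
        elif (~tiled).all():
            g = grp.sort_values("time_h")
            obs = TiledObservation(
                sample_id=str(sample_id),
                operator=str(operators[0]),
                X_seed=float(densities[0]),
                S=S,
                times=g["time_h"].to_numpy(dtype=float),
                total_counts=g["count"].to_numpy(dtype=np.int64),
            )
        else:
            raise ValueError(
                f"sample {sample_id!r} mixes tile-resolved and totals-only rows"
            )
        observations.append(obs)
    return observations


def write_observations_csv(observations, path) -> None:
    """Write observations in the long CSV dialect read by
    :func:`read_observations_csv`."""
    rows = []
    for obs in observations:
        for j, t in enumerate(obs.times):
            if obs.tile_resolved:
                for k in range(N_TILES):
                    rows.append(
                        (obs.sample_id, obs.operator, obs.X_seed, t, k,
                         int(obs.tile_counts[j, k]))
                    )
            else:
                rows.append(
                    (obs.sample_id, obs.operator, obs.X_seed, t, None,
                     int(obs.total_counts[j]))
                )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
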