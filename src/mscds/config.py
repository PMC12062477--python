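"""Run configuration: every tunable of the workflow in one place.

Numeric defaults are the workflow's canonical operating point: quality
specification N_min = 5.0e4 cells / P_max = 0.8, spatial-limitation
constant K_s = 24.7, M = 1000 Monte-Carlo iterations, acceptable risk
pi = 90%, design grid 1500-4500 cells cm^-2 in steps of 375 over harvest
times Day 1-9 every 6 h, NRMSE gate 10%, convergence warning at 0.2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .design_space import ConditionGrid, QualitySpecification
from .growth_model import DEFAULT_KS
from .tile_metrics import DEFAULT_AREA_CM2

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    S: float = DEFAULT_AREA_CM2
    K_s: float = DEFAULT_KS
    N_min: float = 5.0e4
    P_max: float = 0.8
    M: int = 1000
    pi: list = field(default_factory=lambda: [90.0])
    seed: int = 20240101
    level: float = 0.95
    init_mu: float = 0.03
    mode: str = "with_interval"
    sampling: str = "independent"
    nrmse_threshold: float = 10.0
    convergence_threshold: float = 0.2
    X_seed_min: float = 1500.0
    X_seed_max: float = 4500.0
    X_seed_step: float = 375.0
    t_start_day: float = 1.0
    t_end_day: float = 9.0
    t_step_h: float = 6.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def grid(self) -> ConditionGrid:
        n_t = int(round((self.t_end_day - self.t_start_day) * 24.0 / self.t_step_h)) + 1
        return ConditionGrid(
            X_seed_values=np.arange(
                self.X_seed_min, self.X_seed_max + 0.5 * self.X_seed_step, self.X_seed_step
            ),
            t_h_days=np.linspace(self.t_start_day, self.t_end_day, n_t),
            S=self.S,
        )

    def quality_spec(self) -> QualitySpecification:
        return QualitySpecification(N_min=self.N_min, P_max=self.P_max)
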