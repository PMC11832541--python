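"""Pipeline configuration: every tunable analysis parameter in one place.

Defaults reproduce the main analysis (50-volume windows, step 1, 4 initial
volumes dropped, 5-95%/5% density grid, vertex-disjoint paths, signed edge
ranking, 2.5 mm motion cut, 0.30 BFR group cut, chronological age included
only in the brain-age model).  The sensitivity variant — 100-volume windows
and chronological age in every model — is reachable by flags alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    window_volumes: int = 50
    step_volumes: int = 1
    drop_initial: int = 4
    density_start: float = 0.05
    density_stop: float = 0.95
    density_step: float = 0.05
    path_mode: str = "vertex"  # vertex | edge
    rank_mode: str = "signed"  # signed | absolute
    motion_threshold_mm: float = 2.5
    bfr_group_cut: float = 0.30
    include_chron_age: dict = field(
        default_factory=lambda: {
            "thickness": False,
            "gm_volume": False,
            "brain_age": True,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_volumes < 2:
            raise ValueError("window_volumes must be >= 2")
        if self.step_volumes < 1:
            raise ValueError("step_volumes must be >= 1")
        if self.drop_initial < 0:
            raise ValueError("drop_initial must be >= 0")
        if not (0.0 < self.density_start <= self.density_stop <= 1.0):
            raise ValueError("density grid bounds must satisfy 0 < start <= stop <= 1")
        if self.density_step <= 0:
            raise ValueError("density_step must be positive")
        if self.path_mode not in ("vertex", "edge"):
            raise ValueError("path_mode must be 'vertex' or 'edge'")
        if self.rank_mode not in ("signed", "absolute"):
            raise ValueError("rank_mode must be 'signed' or 'absolute'")
        if self.motion_threshold_mm <= 0:
            raise ValueError("motion_threshold_mm must be positive")
        if not (0.0 < self.bfr_group_cut < 1.0):
            raise ValueError("bfr_group_cut must lie in (0, 1)")

    def density_grid(self):
        from .redundancy import DensityGrid

        return DensityGrid(
            DensityGrid.default_densities(
                self.density_start, self.density_stop, self.density_step
            )
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
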