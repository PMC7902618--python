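"""Pipeline configuration: validated, YAML round-trippable.

Centralizes the analysis constants — the (n, m) attribution lags per
disturbance, the retention threshold on relative loss, the Spearman
pruning threshold, bin sizes, ensemble size, gradient resolution and
bootstrap count — together with the per-stage seeds and problem sizes.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class Lags(BaseModel):
    fire: tuple[int, int] = (1, 1)
    windthrow: tuple[int, int] = (1, 1)
    insect: tuple[int, int] = (2, 5)

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"fire": tuple(self.fire), "windthrow": tuple(self.windthrow),
                "insect": tuple(self.insect)}


class Thresholds(BaseModel):
    bl_min: float = 0.05        # strict retention threshold on BL_rel
    spearman: float = 0.8       # |rho| above which one of a pair is pruned
    min_bin: int = 3            # minimum records per retained PC bin
    cover_mask: float = 0.1     # minimum forest cover fraction
    pc_bins: int = 20           # bins per principal-component axis
    n_trees: int = 500          # regression trees per ensemble
    pdp_grid: int = 50          # points per environmental gradient
    n_boot: int = 100           # bootstrap samples for zonal CIs

    @field_validator("bl_min", "spearman", "cover_mask")
    @classmethod
    def _positive_float(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v

    @field_validator("min_bin", "pc_bins", "n_trees", "pdp_grid", "n_boot")
    @classmethod
    def _positive_int(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v


class Seeds(BaseModel):
    simulate: int = 11
    split: int = 23
    train: int = 37
    interpret: int = 41
    predict: int = 53

    def offset(self, delta: int) -> "Seeds":
        return Seeds(**{k: v + delta for k, v in self.model_dump().items()})


class PipelineConfig(BaseModel):
    nx: int = 32
    ny: int = 32
    years_climate: tuple[int, int] = (1979, 2018)
    years_biomass: tuple[int, int] = (2000, 2017)
    n_patches: int = 1500
    disturbances: list[str] = Field(
        default_factory=lambda: ["fire", "windthrow", "insect"])
    per_pft_models: bool = False
    n_hyperparam_draws: int = 32
    interpret_top_k: int = 4  # features entering the interaction analysis
    dynamic_lag: int = 1
    current_window: tuple[int, int] = (2009, 2018)
    lags: Lags = Field(default_factory=Lags)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    seeds: Seeds = Field(default_factory=Seeds)
    out_dir: str = "runs/demo"

    @field_validator("nx", "ny")
    @classmethod
    def _grid(cls, v):
        if v < 4:
            raise ValueError("grid dimensions must be >= 4")
        return v

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def demo_config(out_dir: str = "runs/demo", **overrides) -> PipelineConfig:
    """The default end-to-end demonstration configuration."""
    return PipelineConfig(out_dir=out_dir, **overrides)
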