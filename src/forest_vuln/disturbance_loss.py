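"""Response variable and predictor table for disturbance records.

Each disturbance record (fire, windthrow or insect outbreak) is a delineated
forest patch with an event year. Its vulnerability observation is the
relative biomass loss

    BL_rel = (max(B[t-n..t]) - min(B[t..t+m])) / max(B[t-n..t])

computed on the patch-mean annual biomass series, with backward/forward
lags (n, m) per disturbance type: (1, 1) for fires and windthrows, (2, 5)
for insect outbreaks, whose biomass decline is slow. Only records with
BL_rel > 5% are retained for modelling. Predictors are spatially averaged
over the patch footprint; annually resolved predictors are sampled at the
pre-event year (t - 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .biomass_recon import BiomassStack
from .errors import UndefinedLossError
from .features import DYNAMIC_FEATURES, STATIC_FEATURES

#: (backward, forward) year lags per disturbance type.
DEFAULT_LAGS: dict[str, tuple[int, int]] = {
    "fire": (1, 1),
    "windthrow": (1, 1),
    "insect": (2, 5),
}

BL_REL_MIN = 0.05  # strict retention threshold: BL_rel > 5 %

DISTURBANCE_TYPES = tuple(DEFAULT_LAGS)


@dataclass
class DisturbancePatch:
    """One disturbance event: the analysis unit for model training."""

    id: str
    type: str
    year: int
    cells: np.ndarray  # (n, 2) array of (row, col) grid cells
    area: float  # ha
    pft_fractions: dict[str, float] = field(default_factory=dict)
    clean: bool = True  # False when the footprint overlaps other edits

    def __post_init__(self):
        if self.type not in DISTURBANCE_TYPES:
            raise ValueError(f"unknown disturbance type {self.type!r}")
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=int))
        if self.cells.size == 0:
            raise ValueError("patch footprint is empty")
        if self.area <= 0:
            raise ValueError("patch area must be positive")
        s = sum(self.pft_fractions.values())
        if s > 1 + 1e-9 or any(v < 0 for v in self.pft_fractions.values()):
            raise ValueError("PFT fractions must be non-negative and sum to <= 1")


def patch_biomass_series(stack: BiomassStack, patch: DisturbancePatch) -> pd.Series:
    """Patch-mean biomass per year (arithmetic mean over footprint cells)."""
    rows, cols = patch.cells[:, 0], patch.cells[:, 1]
    ny, nx = stack.biomass.shape[1:]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= ny or cols.max() >= nx:
        raise ValueError("patch footprint outside the grid")
    vals = stack.biomass[:, rows, cols].mean(axis=1)
    return pd.Series(vals, index=stack.years)


def relative_loss(series: pd.Series, t: int, n: int, m: int) -> float:
    """Relative biomass loss for an event at year ``t`` with lags (n, m).

    Positive when biomass dropped; can be <= 0 (later filtered out).
    Raises :class:`UndefinedLossError` when the pre-event maximum is zero.
    """
    years = np.asarray(series.index, dtype=int)
    need = set(range(t - n, t + m + 1))
    if not need.issubset(set(years.tolist())):
        raise ValueError(f"series must cover years [{t - n}, {t + m}]")
    pre = series.loc[t - n:t].to_numpy(dtype=float)
    post = series.loc[t:t + m].to_numpy(dtype=float)
    bmax = pre.max()
    if bmax == 0:
        raise UndefinedLossError(f"pre-event biomass maximum is zero at year {t}")
    return float((bmax - post.min()) / bmax)


def _patch_mean(grid: np.ndarray, patch: DisturbancePatch) -> float:
    rows, cols = patch.cells[:, 0], patch.cells[:, 1]
    return float(np.asarray(grid)[rows, cols].mean())


def assemble_features(patch: DisturbancePatch, static: xr.Dataset,
                      climate: xr.Dataset, year: int,
                      dynamic_lag: int = 1) -> pd.Series:
    """One predictor row for a patch: static grids averaged over the
    footprint, dynamic grids at the pre-event year ``year - dynamic_lag``."""
    row: dict[str, float] = {}
    for name in STATIC_FEATURES:
        if name not in static:
            raise ValueError(f"missing static predictor layer {name!r}")
        row[name] = _patch_mean(static[name].values, patch)
    sample_year = int(year) - int(dynamic_lag)
    for name in DYNAMIC_FEATURES:
        if name not in climate:
            raise ValueError(f"missing dynamic predictor layer {name!r}")
        da = climate[name]
        if sample_year not in da["year"].values:
            raise ValueError(f"climate series does not cover year {sample_year}")
        row[name] = _patch_mean(da.sel(year=sample_year).values, patch)
    return pd.Series(row)


def build_loss_records(stack: BiomassStack, patches: list[DisturbancePatch],
                       static: xr.Dataset, climate: xr.Dataset,
                       lags: dict[str, tuple[int, int]] | None = None,
                       bl_min: float = BL_REL_MIN,
                       dynamic_lag: int = 1,
                       keep_unretained: bool = False) -> pd.DataFrame:
    """Assemble the flat record table: predictors + bl_rel per patch.

    Records with ``bl_rel`` <= ``bl_min`` (strict) are filtered out unless
    ``keep_unretained`` is set, in which case they stay with
    ``retained=False``.
    """
    lags = dict(DEFAULT_LAGS if lags is None else lags)
    rows = []
    for patch in patches:
        n, m = lags[patch.type]
        series = patch_biomass_series(stack, patch)
        try:
            bl = relative_loss(series, patch.year, n, m)
        except UndefinedLossError:
            continue
        feats = assemble_features(patch, static, climate, patch.year,
                                  dynamic_lag=dynamic_lag)
        rec = {"patch_id": patch.id, "type": patch.type, "year": patch.year,
               "area": patch.area, "bl_rel": bl, "retained": bl > bl_min}
        rec.update({f"pft_{k}": v for k, v in patch.pft_fractions.items()})
        rec.update(feats.to_dict())
        rows.append(rec)
    df = pd.DataFrame(rows)
    if not keep_unretained and len(df):
        df = df[df["retained"]].reset_index(drop=True)
    return df
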