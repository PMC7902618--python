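"""Gridded application of vulnerability models over space and time.

Fitted models are run in predictive mode over the grid for each year of
the 1979-2018 window: climate predictors vary annually while forest and
landscape predictors are held at their current (2009-2018 mean) values.
PFT-specific predictions are averaged per cell with PFT cover-fraction
weights; cells with forest cover below 0.1 are masked. Per-cell trends
are OLS slopes with two-sided Mann-Kendall significance, and factorial
simulations (one climate driver dynamic at a time) attribute each cell's
trend to its dominant driver. Zonal statistics are forest-area-weighted
means with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .features import DYNAMIC_FEATURES, STATIC_FEATURES
from .model_training import VulnerabilityModel

COVER_MASK_MIN = 0.1
N_BOOT = 100
MK_MIN_YEARS = 10


# --------------------------------------------------------------------------
# Mann-Kendall


def mann_kendall(series: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Kendall test: returns (S statistic, p value).

    Uses the tie-corrected variance and a continuity-corrected normal
    approximation. A constant series returns (0, 1).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        return 0.0, 1.0
    s = np.sum(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, 1)])
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return float(s), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    from scipy.stats import norm
    p = 2 * norm.sf(abs(z))
    return float(s), float(min(p, 1.0))


def trend(series, years=None) -> tuple[float, float]:
    """(OLS slope per year, Mann-Kendall p) for an annual series.

    Requires at least ``MK_MIN_YEARS`` non-missing values; a constant
    series yields (0, 1).
    """
    y = np.asarray(series, dtype=float)
    t = np.arange(len(y)) if years is None else np.asarray(years, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < MK_MIN_YEARS:
        raise ValueError(f"need at least {MK_MIN_YEARS} non-missing years")
    y, t = y[ok], t[ok]
    if np.all(y == y[0]):
        return 0.0, 1.0
    slope = float(np.polyfit(t, y, 1)[0])
    _, p = mann_kendall(y)
    return slope, p


def theil_sen_slope(series, years=None) -> float:
    """Median of pairwise slopes (robust alternative to the OLS trend)."""
    y = np.asarray(series, dtype=float)
    t = np.arange(len(y)) if years is None else np.asarray(years, dtype=float)
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    i, j = np.triu_indices(len(y), 1)
    dt = t[j] - t[i]
    return float(np.median((y[j] - y[i])[dt != 0] / dt[dt != 0]))


# --------------------------------------------------------------------------
# gridded prediction


@dataclass
class PredictorFields:
    """Inputs of a predictive run: static grids (current values) and the
    annual climate dataset, plus PFT cover fractions."""

    static: xr.Dataset  # static predictor layers (y, x)
    climate: xr.Dataset  # dynamic predictor layers (year, y, x)
    pft_fractions: dict[str, xr.DataArray] = field(default_factory=dict)

    @property
    def shape(self):
        return self.static[list(self.static.data_vars)[0]].shape

    def cover(self) -> np.ndarray:
        if not self.pft_fractions:
            return np.ones(self.shape)
        return sum(f.values for f in self.pft_fractions.values())

    def climate_mean(self, years) -> dict[str, np.ndarray]:
        """Per-variable mean over a year window (the 'current' state)."""
        sel = [y for y in np.atleast_1d(years) if y in self.climate["year"]]
        return {v: self.climate[v].sel(year=sel).mean("year").values
                for v in self.climate.data_vars}

    def feature_grids(self, year: int,
                      frozen: dict[str, np.ndarray] | None = None,
                      dynamic_only: list[str] | None = None) -> dict[str, np.ndarray]:
        """Feature name -> 2-D grid for one year. ``frozen`` supplies the
        current-state values; when ``dynamic_only`` is given, every other
        dynamic variable is frozen too (factorial mode)."""
        out = {}
        for name in STATIC_FEATURES:
            if name in self.static:
                out[name] = self.static[name].values
        for name in DYNAMIC_FEATURES:
            if name not in self.climate:
                continue
            freeze = dynamic_only is not None and name not in dynamic_only
            if freeze:
                out[name] = frozen[name]
            else:
                out[name] = self.climate[name].sel(year=year).values
        return out


def _predict_cells(model: VulnerabilityModel, grids: dict[str, np.ndarray],
                   mask: np.ndarray, with_se: bool):
    X = np.column_stack([grids[f][mask] for f in model.features])
    pbl = model.predict(X)
    se = model.predict_se(X) if with_se else None
    return pbl, se


def predict_grid(models: dict[str, VulnerabilityModel],
                 fields: PredictorFields, year: int,
                 cover_min: float = COVER_MASK_MIN,
                 with_se: bool = True,
                 missing_model: str = "error",
                 frozen: dict[str, np.ndarray] | None = None,
                 dynamic_only: list[str] | None = None):
    """Predict (pbl, se) grids for one year.

    ``models`` maps a PFT name (or "all") to its model; PFT predictions
    are cover-fraction weighted per cell. ``missing_model`` controls what
    happens when a PFT has cover but no model: "error" or
    "skip" (renormalize over the available ones).
    """
    cover = fields.cover()
    mask = cover >= cover_min
    grids = fields.feature_grids(year, frozen=frozen, dynamic_only=dynamic_only)

    ny, nx = cover.shape
    pbl = np.full((ny, nx), np.nan)
    se = np.full((ny, nx), np.nan)
    if not mask.any():
        return pbl, se

    if "all" in models:
        p, s = _predict_cells(models["all"], grids, mask, with_se)
        pbl[mask] = p
        if with_se:
            se[mask] = s
        return pbl, se

    covered = [p for p, f in fields.pft_fractions.items()
               if (f.values[mask] > 0).any()]
    missing = [p for p in covered if p not in models]
    if missing and missing_model == "error":
        raise ValueError(f"no model for covered PFT(s): {missing}")
    num = np.zeros(mask.sum())
    num_se = np.zeros(mask.sum())
    den = np.zeros(mask.sum())
    for pft, model in models.items():
        w = fields.pft_fractions[pft].values[mask]
        p, s = _predict_cells(model, grids, mask, with_se)
        num += w * p
        if with_se:
            num_se += w * s
        den += w
    ok = den > 0
    vals = np.full(mask.sum(), np.nan)
    vals[ok] = num[ok] / den[ok]
    pbl[mask] = vals
    if with_se:
        svals = np.full(mask.sum(), np.nan)
        svals[ok] = num_se[ok] / den[ok]
        se[mask] = svals
    return pbl, se


def predict_series(models: dict[str, VulnerabilityModel],
                   fields: PredictorFields, years,
                   current_window=range(2009, 2019),
                   cover_min: float = COVER_MASK_MIN,
                   with_se: bool = True,
                   dynamic_only: list[str] | None = None) -> xr.Dataset:
    """Annual vulnerability grids over ``years`` (a VulnGrid dataset).

    Climate stays dynamic while static predictors keep their current
    values; with ``dynamic_only`` every other climate variable is frozen
    at its 2009-2018 mean as well (factorial simulation).
    """
    years = [int(y) for y in years]
    frozen = fields.climate_mean(list(current_window))
    pbls, ses = [], []
    for y in years:
        p, s = predict_grid(models, fields, y, cover_min=cover_min,
                            with_se=with_se, frozen=frozen,
                            dynamic_only=dynamic_only)
        pbls.append(p)
        ses.append(s)
    ds = xr.Dataset(
        {"pbl": (("year", "y", "x"), np.stack(pbls)),
         "se": (("year", "y", "x"), np.stack(ses))},
        coords={"year": years},
    )
    ds["forest_mask"] = (("y", "x"), fields.cover() >= cover_min)
    return ds


# --------------------------------------------------------------------------
# zonal statistics


def zonal_stats(grid: np.ndarray, weights: np.ndarray, n_boot: int = N_BOOT,
                seed: int = 0, ci: float = 95.0):
    """Area-weighted mean with a percentile bootstrap CI over cells.

    Returns ``(mean, (lo, hi))``; all-masked input returns NaNs.
    """
    g = np.asarray(grid, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    ok = np.isfinite(g) & np.isfinite(w) & (w > 0)
    if not ok.any():
        return float("nan"), (float("nan"), float("nan"))
    g, w = g[ok], w[ok]
    mean = float(np.average(g, weights=w))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n = len(g)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = np.average(g[idx], weights=w[idx])
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(reps, [half, 100.0 - half])
    return mean, (float(lo), float(hi))


# --------------------------------------------------------------------------
# trends and attribution


def trend_grid(vuln: xr.Dataset) -> xr.Dataset:
    """Per-cell OLS trend (% per year when pbl is a %) and MK p value."""
    years = vuln["year"].values.astype(float)
    pbl = vuln["pbl"].values
    ny, nx = pbl.shape[1:]
    slope = np.full((ny, nx), np.nan)
    pval = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            series = pbl[:, i, j]
            if np.isfinite(series).sum() < MK_MIN_YEARS:
                continue
            slope[i, j], pval[i, j] = trend(series, years)
    return xr.Dataset({"slope": (("y", "x"), slope),
                       "p_value": (("y", "x"), pval)},
                      coords={c: vuln[c] for c in ("y", "x") if c in vuln.coords})


def factorial_attribution(models: dict[str, VulnerabilityModel],
                          fields: PredictorFields, climate_features,
                          years, current_window=range(2009, 2019),
                          cover_min: float = COVER_MASK_MIN,
                          significant_only: bool = False,
                          alpha: float = 0.05,
                          min_slope: float = 1e-12) -> xr.Dataset:
    """Dominant climate driver of the vulnerability trend per cell.

    One factorial run per driver k (only k dynamic); the driver with the
    largest |trend| dominates. Cells where every factorial trend is
    (numerically) zero — or none is MK-significant, when
    ``significant_only`` — get no driver (-1).
    """
    climate_features = list(climate_features)
    if not climate_features:
        raise ValueError("climate feature set K must be non-empty")
    slopes, pvals = [], []
    for k in climate_features:
        run = predict_series(models, fields, years, cover_min=cover_min,
                             current_window=current_window, with_se=False,
                             dynamic_only=[k])
        tg = trend_grid(run)
        slopes.append(tg["slope"].values)
        pvals.append(tg["p_value"].values)
    slopes = np.stack(slopes)  # (k, y, x)
    pvals = np.stack(pvals)
    mag = np.abs(slopes)
    if significant_only:
        mag = np.where(pvals < alpha, mag, 0.0)
    mag = np.where(np.isfinite(mag), mag, 0.0)
    dominant = mag.argmax(axis=0)
    defined = mag.max(axis=0) > min_slope
    dominant = np.where(defined, dominant, -1)
    sign = np.where(
        defined,
        np.sign(np.take_along_axis(slopes, dominant[None, ...].clip(0),
                                   axis=0)[0]),
        np.nan)
    return xr.Dataset({
        "driver_index": (("y", "x"), dominant.astype(np.int32)),
        "driver_sign": (("y", "x"), sign),
        "factorial_slope": (("k", "y", "x"), slopes),
        "factorial_p": (("k", "y", "x"), pvals),
    }, coords={"k": climate_features})


def dominance_fractions(attr: xr.Dataset) -> pd.Series:
    """Area fraction of defined cells where each driver dominates."""
    idx = attr["driver_index"].values
    ok = idx >= 0
    drivers = list(np.asarray(attr["k"].values))
    if not ok.any():
        return pd.Series(0.0, index=drivers)
    counts = np.bincount(idx[ok], minlength=len(drivers))
    return pd.Series(counts / ok.sum(), index=drivers)


# --------------------------------------------------------------------------
# climate envelope


def envelope_mask(fields: PredictorFields, training_records: pd.DataFrame,
                  variables=("tavg_longterm", "pcum")) -> np.ndarray:
    """Boolean grid: inside the observational climate envelope.

    A cell is inside iff each envelope variable (long-term temperature and
    climatological precipitation by default) falls within the [min, max]
    of the training records. Dynamic variables are compared on their
    climatological (time-mean) field.
    """
    inside = np.ones(fields.shape, dtype=bool)
    for name in variables:
        if name in fields.static:
            grid = fields.static[name].values
        elif name in fields.climate:
            grid = fields.climate[name].mean("year").values
        else:
            raise ValueError(f"envelope variable {name!r} not in predictors")
        lo = float(training_records[name].min())
        hi = float(training_records[name].max())
        inside &= (grid >= lo) & (grid <= hi)
    return inside
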