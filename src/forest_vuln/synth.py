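"""Seeded synthetic landscapes, climate series and disturbance records.

The generator emulates the statistical structure the analysis assumes —
a single-date biomass map tied to tree-cover change layers, spatially
smooth static stand/terrain predictors, temporally autocorrelated climate
series with configurable linear trends, and disturbance patches whose
realized relative biomass losses follow a *known* response function

    true_loss = clip( base + sum_i w_i * z_i + sum_(i,j) c_ij * z_i * z_j
                      + noise, 0, 1 )

with z the registry-standardized predictor values. Because the generating
weights, interactions, trends and noise level are known (and written to a
``truth.json`` sidecar), every downstream stage can be tested for recovery
of the truth rather than merely for plausibility.

Two record paths exist:

* :func:`generate_disturbances` places rectangular patch footprints on the
  grid and edits the annual biomass stack so that the loss computation
  applied downstream returns the realized loss;
* :func:`generate_records` draws tabular records directly from the same
  feature distributions and response function, for study conditions whose
  record counts exceed what a desk-scale grid can host.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import biomass_recon as br
from .disturbance_loss import DEFAULT_LAGS, DisturbancePatch, assemble_features
from .features import FEATURES, PFTS, STATIC_FEATURES


# --------------------------------------------------------------------------
# configuration / truth


@dataclass
class GeneratorTruth:
    """Known generating process for one disturbance type."""

    disturbance: str = "fire"
    base: float = 0.3
    response_weights: dict[str, float] = field(default_factory=dict)
    interaction_terms: list[tuple[str, str, float]] = field(default_factory=list)
    noise_features: list[str] = field(default_factory=list)
    noise_sd: float = 0.05
    climate_trends: dict[str, float] = field(default_factory=dict)
    event_rate: float = 100.0  # expected patches per year
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be > 0")
        names = (set(self.response_weights) | set(self.noise_features)
                 | {n for i, j, _ in self.interaction_terms for n in (i, j)})
        unknown = names - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature name(s) in truth: {sorted(unknown)}")

    @property
    def features(self) -> list[str]:
        """All features the generated record tables carry, informative first."""
        out = list(self.response_weights)
        out += [n for n in self.noise_features if n not in out]
        for i, j, _ in self.interaction_terms:
            for n in (i, j):
                if n not in out:
                    out.append(n)
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorTruth":
        d = dict(d)
        d["interaction_terms"] = [tuple(t) for t in d.get("interaction_terms", [])]
        return cls(**d)


def default_truth(disturbance: str = "fire", **overrides) -> GeneratorTruth:
    """Study-condition truths: three informative + three nuisance features,
    response noise of 0.05, intercepts at the Europe-mean vulnerabilities
    per disturbance, and a mild background warming trend."""
    presets = {
        "fire": dict(
            base=0.26,
            response_weights={"tmax": 0.12, "pcum": -0.10, "tree_age": 0.10},
            noise_features=["slope", "elevation", "homogeneity"],
        ),
        "windthrow": dict(
            base=0.30,
            response_weights={"wind_speed": 0.12, "tree_height": 0.10,
                              "pcum": 0.08},
            noise_features=["slope", "elevation", "homogeneity"],
        ),
        "insect": dict(
            base=0.20,
            response_weights={"a_tavg": 0.12, "tree_age": 0.08,
                              "tree_density": -0.08},
            noise_features=["slope", "elevation", "homogeneity"],
        ),
    }
    if disturbance not in presets:
        raise ValueError(f"unknown disturbance type {disturbance!r}")
    kwargs = dict(disturbance=disturbance, noise_sd=0.05,
                  climate_trends={"tavg": 0.02, "tmax": 0.02},
                  **presets[disturbance])
    kwargs.update(overrides)
    return GeneratorTruth(**kwargs)


@dataclass
class LandscapeConfig:
    """Knobs of the landscape generator (defaults are the study conditions)."""

    p_loss: float = 0.08       # pixel probability of a cover-loss event
    p_gain: float = 0.05       # pixel probability of cover gain
    rho_loss_true: float = 2.0  # t/ha per % cover, loss pixels
    rho_gain_true: float = 0.8  # t/ha per % cover, gain pixels
    rho_background: float = 1.8  # t/ha per % cover elsewhere
    tc_mean: float = 60.0
    tc_sd: float = 20.0
    smooth_sigma: float = 3.0  # px, spatial correlation of generated fields
    resolution: float = 100.0  # m per pixel
    gain_window_px: int = 25   # 2.5 km at 100 m
    cover_scale: float = 0.95  # PFT fractions sum to cover * this
    consistent_densities: bool = True  # pin B2010 to the true densities


@dataclass
class ClimateConfig:
    ar_rho: float = 0.3        # AR(1) autocorrelation of annual noise
    noise_scale: float = 0.3   # noise sd as a fraction of the feature sd
    spatial_scale: float = 0.5  # climatology spread as a fraction of sd
    baseline_end: int = 1990   # anomaly baseline: years <= this


# --------------------------------------------------------------------------
# landscape


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially smooth standard field (zero mean, unit sd)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_landscape(seed: int, nx: int, ny: int,
                       config: LandscapeConfig | None = None) -> xr.Dataset:
    """Static layers: tree-cover change, 2010 biomass, stand/terrain
    predictors and PFT cover fractions, on an (ny, nx) grid."""
    if nx < 4 or ny < 4:
        raise ValueError("grid dimensions must be >= 4")
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    shape = (ny, nx)

    tc2000 = np.clip(cfg.tc_mean + cfg.tc_sd
                     * _smooth_field(rng, shape, cfg.smooth_sigma), 0.0, 100.0)

    # mutually exclusive loss/gain assignment from a single uniform draw
    u = rng.random(shape)
    loss_mask = u < cfg.p_loss
    gain_mask = (~loss_mask) & (u < cfg.p_loss + cfg.p_gain)
    loss_year = np.zeros(shape, dtype=np.int32)
    loss_year[loss_mask] = rng.integers(2001, 2018, size=int(loss_mask.sum()))
    tc2000[gain_mask] = 0.0  # gain pixels were non-forest in 2000

    radius = max(1, min(cfg.gain_window_px, max(ny, nx) - 1))
    tc2012_gain = br.tc2012_gain_window(tc2000, gain_mask, radius_px=radius)

    layers = br.TreeCoverLayers(tc2000, loss_year, gain_mask, tc2012_gain)
    tc10 = br.tc2010(layers)
    tc10_gain = br.tc2010_gain(layers)

    b2010 = cfg.rho_background * tc10 * (1 + 0.1 * _smooth_field(rng, shape,
                                                                 cfg.smooth_sigma))
    b2010 = np.clip(b2010, 0.0, None)
    # pixels lost before 2011 carry no biomass in 2010; later losses were intact
    b2010[(loss_year >= 2001) & (loss_year <= 2010)] = 0.0
    if cfg.consistent_densities:
        late_loss = (loss_year >= 2011) & (loss_year <= 2017)
        b2010[late_loss] = cfg.rho_loss_true * tc10[late_loss]
        b2010[gain_mask] = cfg.rho_gain_true * tc10_gain[gain_mask]

    data = {
        "tc2000": (("y", "x"), tc2000),
        "loss_year": (("y", "x"), loss_year),
        "gain_mask": (("y", "x"), gain_mask),
        "tc2012_gain": (("y", "x"), tc2012_gain),
        "b2010": (("y", "x"), b2010),
    }
    for name in STATIC_FEATURES:
        f = FEATURES[name]
        vals = f.mu + f.sd * _smooth_field(rng, shape, cfg.smooth_sigma)
        lo = -np.inf if f.lower is None else f.lower
        hi = np.inf if f.upper is None else f.upper
        data[name] = (("y", "x"), np.clip(vals, lo, hi))

    cover = tc2000 / 100.0
    dirichlet = rng.dirichlet(np.ones(len(PFTS)), size=shape)
    for k, pft in enumerate(PFTS):
        data[f"pft_{pft}"] = (("y", "x"),
                              cfg.cover_scale * cover * dirichlet[..., k])

    ds = xr.Dataset(
        data,
        coords={"y": np.arange(ny), "x": np.arange(nx)},
        attrs={"seed": int(seed), "resolution": cfg.resolution,
               "rho_loss_true": cfg.rho_loss_true,
               "rho_gain_true": cfg.rho_gain_true},
    )
    return ds


def landscape_layers(landscape: xr.Dataset) -> br.TreeCoverLayers:
    """Tree-cover layers view of a generated landscape."""
    return br.TreeCoverLayers(
        landscape["tc2000"].values,
        landscape["loss_year"].values,
        landscape["gain_mask"].values,
        landscape["tc2012_gain"].values,
    )


# --------------------------------------------------------------------------
# climate

#: Series the climate generator produces directly (anomalies are derived).
GENERATED_CLIMATE = ("tmax", "pcum", "wind_speed", "tavg")


def generate_climate(seed: int, years, truth: GeneratorTruth,
                     landscape: xr.Dataset | None = None,
                     shape: tuple[int, int] | None = None,
                     config: ClimateConfig | None = None) -> xr.Dataset:
    """Annual climate grids: climatology + linear trend + AR(1) noise.

    Anomaly variables (``a_tavg``, ``a_pcum``) are computed against the
    mean over the baseline years (<= ``config.baseline_end``; the first
    twelve years when the series starts later).
    """
    cfg = config or ClimateConfig()
    years = [int(y) for y in years]
    if any(b != a + 1 for a, b in zip(years, years[1:])):
        raise ValueError("years must be contiguous")
    unknown = set(truth.climate_trends) - set(GENERATED_CLIMATE)
    if unknown:
        raise ValueError(f"unknown climate variable(s) in truth: {sorted(unknown)}")
    if landscape is not None:
        shape = landscape["tc2000"].shape
    if shape is None:
        raise ValueError("either landscape or shape is required")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    nt = len(years)

    sds = {"tmax": FEATURES["tmax"].sd, "pcum": FEATURES["pcum"].sd,
           "wind_speed": FEATURES["wind_speed"].sd, "tavg": 2.0}
    mus = {"tmax": FEATURES["tmax"].mu, "pcum": FEATURES["pcum"].mu,
           "wind_speed": FEATURES["wind_speed"].mu,
           "tavg": FEATURES["tavg_longterm"].mu}

    data = {}
    for name in GENERATED_CLIMATE:
        if name == "tavg" and landscape is not None:
            clim = landscape["tavg_longterm"].values
        else:
            clim = mus[name] + cfg.spatial_scale * sds[name] \
                * _smooth_field(rng, shape, 3.0)
        trend = truth.climate_trends.get(name, 0.0)
        sigma = cfg.noise_scale * sds[name]
        noise = np.zeros((nt, ny, nx))
        if sigma > 0:
            noise[0] = sigma * rng.standard_normal(shape)
            innov_sd = sigma * np.sqrt(1 - cfg.ar_rho ** 2)
            for k in range(1, nt):
                noise[k] = cfg.ar_rho * noise[k - 1] \
                    + innov_sd * rng.standard_normal(shape)
        series = clim[None, :, :] \
            + trend * (np.asarray(years) - years[0])[:, None, None] + noise
        f = FEATURES.get(name)
        if f is not None and f.lower is not None:
            series = np.clip(series, f.lower, None)
        data[name] = (("year", "y", "x"), series)

    ds = xr.Dataset(data, coords={"year": years,
                                  "y": np.arange(ny), "x": np.arange(nx)})
    base_years = [y for y in years if y <= cfg.baseline_end] or years[:12]
    for src, anom in (("tavg", "a_tavg"), ("pcum", "a_pcum")):
        baseline = ds[src].sel(year=base_years).mean("year")
        ds[anom] = ds[src] - baseline
    ds.attrs.update(seed=int(seed), ar_rho=cfg.ar_rho,
                    baseline_years=[base_years[0], base_years[-1]])
    return ds


# --------------------------------------------------------------------------
# response function


def _standardize(name: str, values):
    f = FEATURES[name]
    return (np.asarray(values, dtype=float) - f.mu) / f.sd


def response(truth: GeneratorTruth, features) -> np.ndarray:
    """Noise-free generating response g evaluated on a feature table
    (DataFrame or mapping of name -> array)."""
    if isinstance(features, pd.DataFrame):
        get = lambda n: features[n].to_numpy(dtype=float)  # noqa: E731
        n_rows = len(features)
    else:
        get = lambda n: np.asarray(features[n], dtype=float)  # noqa: E731
        n_rows = None
    g = None
    for name, w in truth.response_weights.items():
        term = w * _standardize(name, get(name))
        g = term if g is None else g + term
    for i, j, c in truth.interaction_terms:
        term = c * _standardize(i, get(i)) * _standardize(j, get(j))
        g = term if g is None else g + term
    if g is None:
        g = np.zeros(n_rows if n_rows is not None else 1)
    return truth.base + g


def realized_loss(truth: GeneratorTruth, features, rng: np.random.Generator):
    g = response(truth, features)
    eps = rng.normal(0.0, truth.noise_sd, size=np.shape(g)) \
        if truth.noise_sd > 0 else 0.0
    return np.clip(g + eps, 0.0, 1.0)


# --------------------------------------------------------------------------
# tabular records


def generate_records(seed: int, truth: GeneratorTruth, n_records: int,
                     years: tuple[int, int] = (2001, 2016)) -> pd.DataFrame:
    """Record table drawn directly from the generating distributions.

    Same schema as the grid-based loss-record table: predictors, PFT
    fractions, area (ha), event year and realized ``bl_rel``.
    """
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in truth.features:
        f = FEATURES[name]
        vals = rng.normal(f.mu, f.sd, size=n_records)
        lo = -np.inf if f.lower is None else f.lower
        hi = np.inf if f.upper is None else f.upper
        cols[name] = np.clip(vals, lo, hi)
    df = pd.DataFrame(cols, index=range(n_records))
    bl = realized_loss(truth, df, rng)
    meta = pd.DataFrame({
        "patch_id": [f"{truth.disturbance}-{i:06d}" for i in range(n_records)],
        "type": truth.disturbance,
        "year": rng.integers(years[0], years[1] + 1, size=n_records),
        "area": rng.lognormal(mean=1.5, sigma=0.75, size=n_records),
        "bl_rel": bl,
        "retained": bl > 0.05,
    })
    pft = rng.dirichlet(np.ones(len(PFTS)), size=n_records) * 0.95
    for k, name in enumerate(PFTS):
        meta[f"pft_{name}"] = pft[:, k]
    return pd.concat([meta, df], axis=1)


# --------------------------------------------------------------------------
# grid-based disturbance patches


def generate_disturbances(seed: int, truth: GeneratorTruth,
                          stack: br.BiomassStack, landscape: xr.Dataset,
                          climate: xr.Dataset, n_patches: int | None = None,
                          max_patch_size: int = 3, dynamic_lag: int = 1,
                          max_tries: int = 50):
    """Place patches, realize their losses and edit the biomass stack.

    Post-event years in the footprint are scaled by ``1 - true_loss``
    relative to the pre-event state, so the downstream loss computation
    recovers the realized loss on clean (non-overlapping, change-free)
    footprints. Returns ``(patches, edited_stack, truth_table)``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = landscape["tc2000"].shape
    n, m = DEFAULT_LAGS[truth.disturbance]
    y0, y1 = stack.years[0] + max(n, dynamic_lag), stack.years[-1] - m
    if y1 < y0:
        raise ValueError("stack years too short for the disturbance lags")
    if n_patches is None:
        n_patches = int(round(truth.event_rate * (y1 - y0 + 1)))
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")

    edited = stack.copy()
    disturbed = landscape["loss_year"].values > 0
    disturbed = disturbed | landscape["gain_mask"].values
    occupied: dict[tuple[int, int], list[tuple[int, int]]] = {}
    res_ha = (stack.resolution / 100.0) ** 2

    patches, rows = [], []
    for idx in range(n_patches):
        chosen = None
        for attempt in range(max_tries):
            h = int(rng.integers(1, max_patch_size + 1))
            w = int(rng.integers(1, max_patch_size + 1))
            r0 = int(rng.integers(0, ny - h + 1))
            c0 = int(rng.integers(0, nx - w + 1))
            t = int(rng.integers(y0, y1 + 1))
            cells = [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]
            window = (t - n, t + m)
            clean = not any(disturbed[r, c] for r, c in cells)
            if clean:
                for cell in cells:
                    for (a, b) in occupied.get(cell, ()):
                        if window[0] <= b and a <= window[1]:
                            clean = False
                            break
                    if not clean:
                        break
            if clean or attempt == max_tries - 1:
                chosen = (cells, t, window, clean)
                break
        cells, t, window, clean = chosen
        for cell in cells:
            occupied.setdefault(cell, []).append(window)

        cell_arr = np.asarray(cells, dtype=int)
        pft_fr = {p: float(landscape[f"pft_{p}"].values[cell_arr[:, 0],
                                                        cell_arr[:, 1]].mean())
                  for p in PFTS}
        patch = DisturbancePatch(
            id=f"{truth.disturbance}-{idx:05d}", type=truth.disturbance,
            year=t, cells=cell_arr, area=len(cells) * res_ha,
            pft_fractions=pft_fr, clean=clean)

        feats = assemble_features(patch, landscape, climate, t,
                                  dynamic_lag=dynamic_lag)
        loss = float(realized_loss(truth, feats, rng))

        rsel, csel = cell_arr[:, 0], cell_arr[:, 1]
        tidx = edited.years.index(t)
        edited.biomass[tidx:, rsel, csel] *= (1.0 - loss)

        patches.append(patch)
        rows.append({"patch_id": patch.id, "year": t, "clean": clean,
                     "true_loss": loss,
                     "g_value": float(response(truth, feats))})

    return patches, edited, pd.DataFrame(rows)
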