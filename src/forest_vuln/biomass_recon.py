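"""Annual biomass reconstruction from a single-year biomass map and
tree-cover change layers.

A static above-ground biomass map for a reference year (2010) is combined
with tree-cover layers — tree cover for 2000, the year of complete cover
loss per pixel, and a binary 2000-2012 cover-gain mask — to produce annual
biomass grids over 2000-2017. The bridge between cover change (in %) and
biomass change (in t/ha) is a pair of density fields: biomass per percent
of cover lost (rho_loss) and gained (rho_gain), estimated on the pixels
where the change is observed and spatialized by taking the median on a
coarse grid.

The reconstruction for year ``t`` is

    B_t = B_2010 + alpha * rho_loss * TC_loss(t)
               - rho_gain * TC_gain_2010 * (2010 - t) / 10

where ``TC_loss(t)`` is the cover lost between ``t`` and 2010 (for t before
2010) or between 2010 and ``t`` (after), ``alpha`` is +1 before the
configured boundary year and -1 from it on, and the gain term ramps the
static 2010 gain cover linearly in time. Negative results are clipped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ReconstructionError

#: Exact ratio of the 10-year ramp to the 12-year gain period
#: (TC_gain_2010 / 10 = TC_gain_2012 / 12); prints as 0.83.
GAIN_RAMP_FACTOR = 10.0 / 12.0

REFERENCE_YEAR = 2010
YEAR_MIN, YEAR_MAX = 2000, 2017


@dataclass
class TreeCoverLayers:
    """Tree-cover change layers on a common grid.

    tc2000       -- canopy cover in 2000, percent per pixel.
    loss_year    -- year of complete cover loss (0 = never lost).
    gain_mask    -- boolean, non-forest to forest change over 2000-2012.
    tc2012_gain  -- maximum potential cover (%) for gain pixels, taken as
                    the max cover within a moving circular window.
    """

    tc2000: np.ndarray
    loss_year: np.ndarray
    gain_mask: np.ndarray
    tc2012_gain: np.ndarray | None = None

    def __post_init__(self):
        self.tc2000 = np.asarray(self.tc2000, dtype=float)
        self.loss_year = np.asarray(self.loss_year)
        self.gain_mask = np.asarray(self.gain_mask, dtype=bool)
        shapes = {self.tc2000.shape, self.loss_year.shape, self.gain_mask.shape}
        if self.tc2012_gain is not None:
            self.tc2012_gain = np.asarray(self.tc2012_gain, dtype=float)
            shapes.add(self.tc2012_gain.shape)
        if len(shapes) != 1:
            raise ValueError("tree-cover layers must share a common shape")
        if np.nanmin(self.tc2000) < 0 or np.nanmax(self.tc2000) > 100:
            raise ValueError("tc2000 must lie in [0, 100] percent")
        ly = self.loss_year[self.loss_year != 0]
        if ly.size and (ly.min() < YEAR_MIN + 1 or ly.max() > YEAR_MAX):
            raise ValueError("loss_year must be 0 or within [2001, 2017]")

    @property
    def shape(self):
        return self.tc2000.shape


@dataclass
class DensityGrids:
    """Spatialized biomass densities, t/ha per percent cover (NaN = undefined)."""

    rho_loss: np.ndarray
    rho_gain: np.ndarray


@dataclass
class BiomassStack:
    """Annual biomass grids (t/ha), one 2-D layer per year."""

    years: list[int]
    biomass: np.ndarray  # (year, y, x)
    resolution: float = 100.0  # length units per pixel
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = [int(y) for y in self.years]
        self.biomass = np.asarray(self.biomass, dtype=float)
        if any(b >= a for a, b in zip(self.years[1:], self.years)):
            raise ValueError("years must be strictly increasing")
        if self.biomass.shape[0] != len(self.years):
            raise ValueError("biomass first axis must match years")
        if np.nanmin(self.biomass) < 0:
            raise ValueError("biomass must be non-negative")

    def layer(self, year: int) -> np.ndarray:
        return self.biomass[self.years.index(int(year))]

    def copy(self) -> "BiomassStack":
        return BiomassStack(list(self.years), self.biomass.copy(),
                            self.resolution, dict(self.attrs))


def tc2010(layers: TreeCoverLayers) -> np.ndarray:
    """Tree cover in 2010: the 2000 cover with 2001-2010 loss pixels zeroed."""
    lost = (layers.loss_year >= 2001) & (layers.loss_year <= 2010)
    out = layers.tc2000.copy()
    out[lost] = 0.0
    return out


def tc2012_gain_window(tc2000: np.ndarray, gain_mask: np.ndarray,
                       radius_px: int = 25) -> np.ndarray:
    """Maximum potential cover for gain pixels: max cover in a circular window.

    ``radius_px`` defaults to 25 pixels (2.5 km at 100 m resolution).
    Non-gain pixels are NaN.
    """
    yy, xx = np.ogrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    footprint = (yy * yy + xx * xx) <= radius_px * radius_px
    local_max = ndimage.maximum_filter(tc2000, footprint=footprint, mode="nearest")
    out = np.full(tc2000.shape, np.nan)
    out[gain_mask] = local_max[gain_mask]
    return out


def tc2010_gain(layers: TreeCoverLayers,
                factor: float = GAIN_RAMP_FACTOR) -> np.ndarray:
    """Gain-pixel cover in 2010: 10/12 of the 2000-2012 linear cover ramp."""
    if layers.tc2012_gain is None:
        raise ValueError("layers.tc2012_gain is required (set it or derive it "
                         "with tc2012_gain_window)")
    out = np.full(layers.shape, np.nan)
    out[layers.gain_mask] = factor * layers.tc2012_gain[layers.gain_mask]
    return out


def _coarse_median_fill(ratios: np.ndarray, block: int,
                        what: str = "density") -> np.ndarray:
    """Median of defined pixel ratios per coarse block, nearest-filled and
    broadcast back to the fine grid."""
    ny, nx = ratios.shape
    nby, nbx = -(-ny // block), -(-nx // block)
    coarse = np.full((nby, nbx), np.nan)
    for i in range(nby):
        for j in range(nbx):
            cell = ratios[i * block:(i + 1) * block, j * block:(j + 1) * block]
            vals = cell[np.isfinite(cell)]
            if vals.size:
                coarse[i, j] = np.median(vals)
    defined = np.isfinite(coarse)
    if not defined.any():
        raise ReconstructionError(
            f"no defined {what} pixels anywhere in the domain")
    if not defined.all():
        # fill empty coarse cells from the nearest defined cell
        _, (iy, ix) = ndimage.distance_transform_edt(~defined, return_indices=True)
        coarse = coarse[iy, ix]
    fine = np.repeat(np.repeat(coarse, block, axis=0), block, axis=1)
    return fine[:ny, :nx]


def densities(b2010: np.ndarray, layers: TreeCoverLayers,
              coarse_block: int = 8,
              gain_factor: float = GAIN_RAMP_FACTOR) -> DensityGrids:
    """Estimate rho_loss and rho_gain and spatialize them.

    rho_loss uses pixels intact in 2010 but lost during 2011-2017;
    rho_gain uses the gain pixels. Pixels with zero cover in the denominator
    are excluded. Each coarse block takes the median of its defined pixel
    ratios; blocks with none are nearest-filled.
    """
    b2010 = np.asarray(b2010, dtype=float)
    if b2010.shape != layers.shape:
        raise ValueError("b2010 and tree-cover layers must share shape")
    tc10 = tc2010(layers)

    if (layers.loss_year > 0).any():
        loss_mask = (layers.loss_year >= 2011) & (layers.loss_year <= 2017)
        ratio_loss = np.full(layers.shape, np.nan)
        ok = loss_mask & (tc10 > 0)
        ratio_loss[ok] = b2010[ok] / tc10[ok]
        rho_loss = _coarse_median_fill(ratio_loss, coarse_block, "loss-density")
    else:
        # a change-free domain needs no density: the loss term vanishes
        rho_loss = np.zeros(layers.shape)

    if layers.gain_mask.any():
        tcg = tc2010_gain(layers, factor=gain_factor)
        ratio_gain = np.full(layers.shape, np.nan)
        ok = layers.gain_mask & (tcg > 0)
        ratio_gain[ok] = b2010[ok] / tcg[ok]
        rho_gain = _coarse_median_fill(ratio_gain, coarse_block, "gain-density")
    else:
        rho_gain = np.zeros(layers.shape)

    return DensityGrids(rho_loss=rho_loss, rho_gain=rho_gain)


def tc_t_loss(layers: TreeCoverLayers, t: int) -> np.ndarray:
    """Cover lost between ``t`` and 2010 (t < 2010) or 2010 and ``t`` (t > 2010)."""
    ly = layers.loss_year
    if t < REFERENCE_YEAR:
        between = (ly > t) & (ly <= REFERENCE_YEAR)
    else:
        between = (ly > REFERENCE_YEAR) & (ly <= t)
    out = np.zeros(layers.shape)
    out[between] = layers.tc2000[between]
    return out


def annual_biomass(b2010: np.ndarray, dens: DensityGrids,
                   layers: TreeCoverLayers, t: int,
                   alpha_boundary_year: int = 2009,
                   gain_factor: float = GAIN_RAMP_FACTOR,
                   gain_mode: str = "static") -> np.ndarray:
    """Biomass grid for year ``t`` (2000-2017), clipped at zero.

    ``alpha_boundary_year`` controls the sign switch of the loss term:
    alpha = +1 for t < boundary, -1 otherwise (the literal reading of the
    reconstruction rule leaves 2009 on the negative side).

    ``gain_mode`` selects the reading of the gain-cover term: "static"
    (default) uses the fixed 2010 gain cover with all time dependence in
    the (2010 - t)/10 ramp; "per-year" additionally evaluates the gain
    cover on its own 2000-2012 linear ramp at year ``t`` (a double time
    scaling kept only for comparison).
    """
    t = int(t)
    if not YEAR_MIN <= t <= YEAR_MAX:
        raise ValueError(f"year {t} outside [{YEAR_MIN}, {YEAR_MAX}]")
    if gain_mode not in ("static", "per-year"):
        raise ValueError(f"unknown gain_mode {gain_mode!r}")
    b2010 = np.asarray(b2010, dtype=float)
    alpha = 1.0 if t < alpha_boundary_year else -1.0
    tcl = tc_t_loss(layers, t)

    gain_term = np.zeros(layers.shape)
    gm = layers.gain_mask
    if gm.any():
        if gain_mode == "static":
            tcg = tc2010_gain(layers, factor=gain_factor)
        else:
            tcg = np.zeros(layers.shape)
            tcg[gm] = layers.tc2012_gain[gm] * (t - 2000) / 12.0
        gain_term[gm] = dens.rho_gain[gm] * tcg[gm] \
            * (REFERENCE_YEAR - t) / 10.0

    out = b2010 + alpha * dens.rho_loss * tcl - gain_term
    return np.clip(out, 0.0, None)


def reconstruct_stack(b2010: np.ndarray, layers: TreeCoverLayers,
                      years=range(YEAR_MIN, YEAR_MAX + 1),
                      dens: DensityGrids | None = None,
                      resolution: float = 100.0,
                      alpha_boundary_year: int = 2009,
                      coarse_block: int = 8,
                      gain_factor: float = GAIN_RAMP_FACTOR) -> BiomassStack:
    """Full annual reconstruction; estimates densities unless provided."""
    if dens is None:
        dens = densities(b2010, layers, coarse_block=coarse_block,
                         gain_factor=gain_factor)
    years = [int(y) for y in years]
    grids = [annual_biomass(b2010, dens, layers, t,
                            alpha_boundary_year=alpha_boundary_year,
                            gain_factor=gain_factor)
             for t in years]
    return BiomassStack(years, np.stack(grids), resolution=resolution)
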