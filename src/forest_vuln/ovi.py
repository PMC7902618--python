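"""Overall vulnerability index: combining disturbance-specific potential
losses under independence.

Treating the disturbance-specific potential relative biomass losses as
probabilities of mutually non-exclusive, independent events spread
homogeneously within a cell, the combined loss is the inclusion-exclusion
union, which collapses algebraically to the complement product

    OVI = 1 - prod_p (1 - PBL_p).

The module also decomposes the index into per-disturbance contributions,
converts relative to absolute biomass loss, and builds the space-time
integrated index (product of min-max-normalized current OVI and OVI
trend) that flags high-and-worsening cells.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np


def combine(pbls) -> float | np.ndarray:
    """Union of independent potential losses: ``1 - prod(1 - p)``.

    Accepts a sequence of scalars (returns a scalar) or of equally shaped
    grids (returns a grid; NaN where any input is NaN).
    """
    arrays = [np.asarray(p, dtype=float) for p in pbls]
    if not arrays:
        raise ValueError("need at least one disturbance")
    for a in arrays:
        finite = a[np.isfinite(a)] if a.ndim else (a if np.isfinite(a) else None)
        if finite is not None and finite.size and \
                (np.min(finite) < 0 or np.max(finite) > 1):
            raise ValueError("potential losses must lie in [0, 1]")
    out = 1.0 - np.prod([1.0 - a for a in arrays], axis=0)
    return float(out) if out.ndim == 0 else out


def combine_inclusion_exclusion(pbls) -> float:
    """Explicit inclusion-exclusion expansion over all subsets, with
    independence intersections (products). Algebraically identical to
    :func:`combine`; kept as the literal union formula for scalars."""
    p = [float(v) for v in pbls]
    if any(v < 0 or v > 1 for v in p):
        raise ValueError("potential losses must lie in [0, 1]")
    total = 0.0
    for q in range(1, len(p) + 1):
        sign = (-1.0) ** (q - 1)
        for subset in itertools.combinations(p, q):
            total += sign * np.prod(subset)
    return float(total)


def contributions(pbls: dict[str, float],
                  method: str = "share") -> dict[str, float]:
    """Per-disturbance contribution (%) to the combined vulnerability.

    "share" (default) is each disturbance's proportion of the sum of the
    individual potential losses. "shapley" attributes the union value
    exactly by Shapley decomposition. All-zero input yields NaNs.
    """
    names = list(pbls)
    vals = np.array([pbls[n] for n in names], dtype=float)
    if vals.sum() == 0:
        return {n: float("nan") for n in names}
    if method == "share":
        shares = 100.0 * vals / vals.sum()
    elif method == "shapley":
        shares = 100.0 * _shapley(vals) / combine(vals)
    else:
        raise ValueError(f"unknown contribution method {method!r}")
    return dict(zip(names, shares))


def _shapley(vals: np.ndarray) -> np.ndarray:
    """Shapley values of the union 'game' v(S) = 1 - prod_{i in S}(1-p_i)."""
    n = len(vals)
    out = np.zeros(n)
    for perm in itertools.permutations(range(n)):
        running = 0.0
        for i in perm:
            new = 1.0 - (1.0 - running) * (1.0 - vals[i])
            out[i] += new - running
            running = new
    return out / math.factorial(n)


def absolute_loss(ovi_pbl: np.ndarray, biomass: np.ndarray,
                  mask: np.ndarray | None = None):
    """Cellwise absolute loss (t) and the masked domain total.

    Returns ``(grid, total)``; cells outside ``mask`` count 0 in the total.
    """
    ovi_pbl = np.asarray(ovi_pbl, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if ovi_pbl.shape != biomass.shape:
        raise ValueError("vulnerability and biomass grids must share shape")
    grid = ovi_pbl * biomass
    use = np.isfinite(grid)
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    return grid, float(grid[use].sum())


def _minmax(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = grid[mask]
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    out = np.full(grid.shape, np.nan)
    if hi == lo:
        warnings.warn("constant grid in space-time index: factor set to 0")
        out[mask] = 0.0
    else:
        out[mask] = (grid[mask] - lo) / (hi - lo)
    return out


def spacetime_index(current_ovi: np.ndarray, ovi_trend: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Product of the min-max-normalized current index and its trend.

    Values near 1 mark cells that are both highly vulnerable now and on
    the steepest worsening trajectory.
    """
    current_ovi = np.asarray(current_ovi, dtype=float)
    ovi_trend = np.asarray(ovi_trend, dtype=float)
    if current_ovi.shape != ovi_trend.shape:
        raise ValueError("grids must share shape")
    if mask is None:
        mask = np.isfinite(current_ovi) & np.isfinite(ovi_trend)
    else:
        mask = np.asarray(mask, dtype=bool) \
            & np.isfinite(current_ovi) & np.isfinite(ovi_trend)
    return _minmax(current_ovi, mask) * _minmax(ovi_trend, mask)
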