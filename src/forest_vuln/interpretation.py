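"""Model-agnostic interpretation of fitted vulnerability models.

* zero-centred partial dependence curves (PDP) over 50-point gradients;
* Friedman's H-statistic for the strength of two-way interactions,
  averaged over predictor-category combinations;
* the interaction amplification Delta-P: relative change of the response
  surface peak against its additive (no-interaction) decomposition;
* per-location ICE slopes ("local sensitivity") and the category-level
  marginal contribution Z_marg, the category share of total |slope|.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CATEGORIES
from .model_training import VulnerabilityModel

PDP_GRID_SIZE = 50
H_SUBSAMPLE = 500


@dataclass
class PDPCurve:
    feature: str
    grid: np.ndarray
    pd_values: np.ndarray
    centred: bool


@dataclass
class InteractionReport:
    pairwise_h: dict[tuple[str, str], float]
    category_means: pd.DataFrame
    delta_p: dict[tuple[str, str], float]


def _data_matrix(model: VulnerabilityModel, data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[model.features].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def feature_grid(model: VulnerabilityModel, feature: str, data=None,
                 size: int = PDP_GRID_SIZE) -> np.ndarray:
    """Equally spaced gradient spanning the observed feature range."""
    if data is not None:
        col = (data[feature] if isinstance(data, pd.DataFrame)
               else data[:, model.features.index(feature)])
        lo, hi = float(np.min(col)), float(np.max(col))
    else:
        lo, hi = model.feature_ranges[feature]
    return np.linspace(lo, hi, size)


def _check_features(model: VulnerabilityModel, *names):
    for n in names:
        if n not in model.features:
            raise ValueError(f"feature {n!r} is not a model predictor")


def pdp(model: VulnerabilityModel, feature: str, data, centre: bool = True,
        grid_size: int = PDP_GRID_SIZE) -> PDPCurve:
    """Average model response as ``feature`` is swept over its gradient."""
    _check_features(model, feature)
    X = _data_matrix(model, data)
    grid = feature_grid(model, feature, data, size=grid_size)
    k = model.features.index(feature)
    # one batched prediction over (grid x rows)
    rep = np.repeat(X[None, :, :], len(grid), axis=0)
    rep[:, :, k] = grid[:, None]
    preds = model.predict(rep.reshape(-1, X.shape[1])).reshape(len(grid), -1)
    curve = preds.mean(axis=1)
    if centre:
        curve = curve - curve.mean()
    return PDPCurve(feature=feature, grid=grid, pd_values=curve, centred=centre)


def _subsample(X: np.ndarray, n: int, seed: int) -> np.ndarray:
    if len(X) <= n:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(len(X), size=n, replace=False)]


def _pd_on_values(model, X, k_cols, value_rows) -> np.ndarray:
    """Partial dependence at arbitrary coordinate tuples for columns
    ``k_cols``; one batched ensemble call."""
    value_rows = np.atleast_2d(value_rows)
    rep = np.repeat(X[None, :, :], len(value_rows), axis=0)
    for j, k in enumerate(k_cols):
        rep[:, :, k] = value_rows[:, j][:, None]
    preds = model.predict(rep.reshape(-1, X.shape[1]))
    return preds.reshape(len(value_rows), -1).mean(axis=1)


def h_pairwise(model: VulnerabilityModel, feature_i: str, feature_j: str,
               data, grid_size: int = PDP_GRID_SIZE,
               n_rows: int = H_SUBSAMPLE, seed: int = 0) -> float:
    """Friedman H for one feature pair, evaluated at the data points with
    coordinates snapped to the 50-point gradients.

    H^2 = sum[(PDij - PDi - PDj)^2] / sum[PDij^2] with centred partial
    dependences; returns H in [0, 1] (0 with a warning when the two-way
    surface is flat).
    """
    _check_features(model, feature_i, feature_j)
    X = _subsample(_data_matrix(model, data), n_rows, seed)
    ki = model.features.index(feature_i)
    kj = model.features.index(feature_j)
    gi = feature_grid(model, feature_i, data, size=grid_size)
    gj = feature_grid(model, feature_j, data, size=grid_size)

    def snap(vals, grid):
        return grid[np.abs(vals[:, None] - grid[None, :]).argmin(axis=1)]

    xi, xj = snap(X[:, ki], gi), snap(X[:, kj], gj)

    pdi_grid = _pd_on_values(model, X, [ki], gi[:, None])
    pdj_grid = _pd_on_values(model, X, [kj], gj[:, None])
    pairs, inverse = np.unique(np.column_stack([xi, xj]), axis=0,
                               return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    pdij_pairs = _pd_on_values(model, X, [ki, kj], pairs)

    pdi = pdi_grid[np.searchsorted(gi, xi)]
    pdj = pdj_grid[np.searchsorted(gj, xj)]
    pdij = pdij_pairs[inverse]
    pdi, pdj, pdij = (v - v.mean() for v in (pdi, pdj, pdij))

    denom = np.sum(pdij ** 2)
    if denom <= 0:
        warnings.warn(f"flat two-way partial dependence for "
                      f"({feature_i}, {feature_j}); H reported as 0")
        return 0.0
    h2 = np.sum((pdij - pdi - pdj) ** 2) / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


def interaction_matrix(model: VulnerabilityModel, data,
                       features=None, seed: int = 0,
                       n_rows: int = H_SUBSAMPLE) -> dict[tuple[str, str], float]:
    """Pairwise H for all (or the given) model features."""
    feats = list(features or model.features)
    return {(a, b): h_pairwise(model, a, b, data, n_rows=n_rows, seed=seed)
            for a, b in itertools.combinations(feats, 2)}


def category_interaction_means(pairwise_h: dict[tuple[str, str], float],
                               categories: dict[str, str]) -> pd.DataFrame:
    """Mean H per (category, category) combination, plus an 'all' cell."""
    cats = list(CATEGORIES)
    mat = pd.DataFrame(np.nan, index=cats + ["all"], columns=cats + ["all"])
    buckets: dict[tuple[str, str], list[float]] = {}
    for (a, b), h in pairwise_h.items():
        ca, cb = sorted((categories[a], categories[b]))
        buckets.setdefault((ca, cb), []).append(h)
    for (ca, cb), vals in buckets.items():
        mat.loc[ca, cb] = mat.loc[cb, ca] = float(np.mean(vals))
    if pairwise_h:
        mat.loc["all", "all"] = float(np.mean(list(pairwise_h.values())))
    return mat


def delta_p(model: VulnerabilityModel, feature_i: str, feature_j: str,
            data, grid_size: int = PDP_GRID_SIZE,
            n_rows: int = H_SUBSAMPLE, seed: int = 0) -> float:
    """Peak amplification (%) of the two-way response surface relative to
    its additive decomposition, on centred surfaces over the shared grid.

    Positive values mean the interaction amplifies the response peak.
    NaN when the additive reference peak is zero.
    """
    _check_features(model, feature_i, feature_j)
    X = _subsample(_data_matrix(model, data), n_rows, seed)
    ki = model.features.index(feature_i)
    kj = model.features.index(feature_j)
    gi = feature_grid(model, feature_i, data, size=grid_size)
    gj = feature_grid(model, feature_j, data, size=grid_size)

    pdi = _pd_on_values(model, X, [ki], gi[:, None])
    pdj = _pd_on_values(model, X, [kj], gj[:, None])
    mesh = np.array([[a, b] for a in gi for b in gj])
    pdij = _pd_on_values(model, X, [ki, kj], mesh).reshape(len(gi), len(gj))

    pdi, pdj, pdij = pdi - pdi.mean(), pdj - pdj.mean(), pdij - pdij.mean()
    additive = pdi[:, None] + pdj[None, :]
    peak_add = additive.max()
    if peak_add == 0:
        return float("nan")
    return float(100.0 * (pdij.max() - peak_add) / abs(peak_add))


def ice_sensitivity(model: VulnerabilityModel, feature: str, row,
                    grid: np.ndarray | None = None,
                    grid_size: int = PDP_GRID_SIZE) -> float:
    """OLS slope of one location's ICE curve over the feature gradient.

    ``row`` is a single covariate vector (Series or 1-D array); the grid
    defaults to the model's training range.
    """
    _check_features(model, feature)
    if isinstance(row, pd.Series):
        row = row[model.features].to_numpy(dtype=float)
    row = np.asarray(row, dtype=float).ravel()
    if grid is None:
        grid = feature_grid(model, feature, size=grid_size)
    k = model.features.index(feature)
    M = np.repeat(row[None, :], len(grid), axis=0)
    M[:, k] = grid
    curve = model.predict(M)
    if grid.max() == grid.min():
        return 0.0
    return float(np.polyfit(grid, curve, 1)[0])


def z_marg(slopes: dict[str, float], categories: dict[str, str]) -> dict[str, float]:
    """Category shares (%) of the total absolute local sensitivity.

    Shares sum to 100 where any slope is nonzero; all-NaN otherwise.
    """
    total = sum(abs(s) for s in slopes.values())
    if total == 0:
        return {c: float("nan") for c in CATEGORIES}
    out = {c: 0.0 for c in CATEGORIES}
    for name, s in slopes.items():
        out[categories[name]] += abs(s)
    return {c: 100.0 * v / total for c, v in out.items()}
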