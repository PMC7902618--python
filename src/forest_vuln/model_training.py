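"""Calibration and validation of tree-ensemble vulnerability models.

The record table is turned into a model through the following chain:

1. missing predictor values are imputed with the per-variable median;
2. records are resampled into bins along the first three principal
   components of the standardized predictors (20 equal-width bins per
   axis over the pooled range), after a per-year random 60/40
   train/test split; bin aggregates are area-weighted means and bins
   with fewer than three records are dropped — this tempers the spatial
   dependence of clustered disturbance records;
3. a two-stage feature selection prunes one of every predictor pair with
   |Spearman rho| > 0.8 (keeping the more important one) and then walks a
   backward-elimination path, keeping the subset that maximizes test R^2;
4. a random forest of 500 regression trees is fitted on the training
   bins (sample weights = bin area totals, times the PFT cover fraction
   for PFT-specific models), with tree depth and per-split feature count
   chosen by a seeded randomized search scored on out-of-bag error;
5. the held-out binned test set yields R^2, RMSE, NRMSE, PBIAS and
   per-bin relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .errors import InsufficientDataError
from .features import PFTS

N_TREES = 500
N_PC_BINS = 20
MIN_BIN_RECORDS = 3
SPEARMAN_MAX = 0.8
TRAIN_FRACTION = 0.6
PFT_MIN_FRACTION = 0.05


# --------------------------------------------------------------------------
# imputation


def impute_missing(records: pd.DataFrame, feature_cols) -> pd.DataFrame:
    """Fill missing predictor values with the per-variable median."""
    out = records.copy()
    for col in feature_cols:
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"variable {col!r} has no observed values")
        out[col] = vals.fillna(vals.median())
    return out


# --------------------------------------------------------------------------
# PC-space binned resampling with stratified split


@dataclass
class BinnedSet:
    """Aggregated records on the 3-D principal-component lattice."""

    bins: pd.DataFrame  # features + bl_rel + weight + n_records + pft_* + pc0..2
    feature_cols: list[str]
    n_records: int  # records contributing to retained bins
    dropped_weight: float  # total area weight in dropped (<3 record) bins
    n_dropped_bins: int

    def __len__(self):
        return len(self.bins)

    @property
    def X(self) -> pd.DataFrame:
        return self.bins[self.feature_cols]

    @property
    def y(self) -> np.ndarray:
        return self.bins["bl_rel"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.bins["weight"].to_numpy()


def _bin_index(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _aggregate_bins(df: pd.DataFrame, pc_cols, feature_cols,
                    min_records: int) -> tuple[pd.DataFrame, float, int]:
    pft_cols = [c for c in df.columns if c.startswith("pft_")]
    value_cols = list(feature_cols) + ["bl_rel"] + pft_cols
    w = df["area"].to_numpy(dtype=float)

    grouped = df.assign(_w=w).groupby(pc_cols, sort=True)
    rows = []
    dropped_weight, n_dropped = 0.0, 0
    for key, sub in grouped:
        tw = sub["_w"].sum()
        if len(sub) < min_records:
            dropped_weight += tw
            n_dropped += 1
            continue
        rec = {c: np.average(sub[c], weights=sub["_w"]) for c in value_cols}
        s = sum(rec[c] for c in pft_cols)
        if s > 0:
            for c in pft_cols:
                rec[c] /= s
        rec.update(dict(zip(["pc0", "pc1", "pc2"], np.atleast_1d(key))))
        rec["weight"] = tw
        rec["n_records"] = len(sub)
        rows.append(rec)
    if not rows:
        cols = value_cols + ["pc0", "pc1", "pc2", "weight", "n_records"]
        return pd.DataFrame(columns=cols), dropped_weight, n_dropped
    return pd.DataFrame(rows), dropped_weight, n_dropped


def year_stratified_mask(records: pd.DataFrame, seed: int,
                         train_frac: float = TRAIN_FRACTION) -> np.ndarray:
    """Boolean train mask: per-year random 60/40 split without replacement.

    Years with fewer than two records go wholly to training.
    """
    rng = np.random.default_rng(seed)
    in_train = np.zeros(len(records), dtype=bool)
    groups = records.groupby("year").indices
    for year_key in sorted(groups):
        idx = np.asarray(groups[year_key])
        if len(idx) < 2:
            in_train[idx] = True
            continue
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = rng.choice(idx, size=n_train, replace=False)
        in_train[chosen] = True
    return in_train


def pc_bin_split(records: pd.DataFrame, feature_cols, seed: int,
                 n_bins: int = N_PC_BINS, n_pcs: int = 3,
                 min_records: int = MIN_BIN_RECORDS,
                 train_frac: float = TRAIN_FRACTION) -> tuple[BinnedSet, BinnedSet]:
    """Split records 60/40 per year and bin each subset in PC space.

    PC axes and bin edges are derived from the pooled (pre-split) records
    so train and test share the same lattice.
    """
    feature_cols = list(feature_cols)
    if len(records) < max(3, n_pcs):
        raise ValueError("need at least as many records as principal components")
    if "area" not in records:
        records = records.assign(area=1.0)

    X = records[feature_cols].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_pcs = min(n_pcs, len(feature_cols))
    pca = PCA(n_components=n_pcs, random_state=0)
    scores = pca.fit_transform(Z)
    if n_pcs < 3:  # pad so the lattice is always 3-D
        scores = np.hstack([scores, np.zeros((len(records), 3 - n_pcs))])

    lows, highs = scores.min(axis=0), scores.max(axis=0)
    pc_cols = ["_pc0", "_pc1", "_pc2"]
    annotated = records.copy()
    for k, col in enumerate(pc_cols):
        annotated[col] = _bin_index(scores[:, k], lows[k], highs[k], n_bins)

    in_train = year_stratified_mask(annotated, seed, train_frac)

    out = []
    for mask in (in_train, ~in_train):
        sub = annotated[mask]
        bins, dropped_w, n_dropped = _aggregate_bins(sub, pc_cols, feature_cols,
                                                     min_records)
        bins = bins.rename(columns=dict(zip(pc_cols, ["pc0", "pc1", "pc2"])))
        n_binned = int(bins["n_records"].sum()) if len(bins) else 0
        out.append(BinnedSet(bins, feature_cols, n_binned, dropped_w, n_dropped))
    return out[0], out[1]


def as_binned(records: pd.DataFrame, feature_cols) -> BinnedSet:
    """Wrap raw (unbinned) records as a degenerate one-record-per-bin set,
    for fitting or validating directly on dense record tables."""
    feature_cols = list(feature_cols)
    pft_cols = [c for c in records.columns if c.startswith("pft_")]
    bins = records[feature_cols + ["bl_rel"] + pft_cols].copy()
    bins["weight"] = records["area"].to_numpy(dtype=float) \
        if "area" in records else 1.0
    bins["n_records"] = 1
    for c in ("pc0", "pc1", "pc2"):
        bins[c] = 0
    return BinnedSet(bins.reset_index(drop=True), feature_cols,
                     n_records=len(bins), dropped_weight=0.0, n_dropped_bins=0)


# --------------------------------------------------------------------------
# fitting


@dataclass
class VulnerabilityModel:
    """Fitted ensemble for one (disturbance, PFT) combination."""

    disturbance: str
    pft: str  # a PFT name or "all"
    features: list[str]
    ensemble: RandomForestRegressor
    hyperparams: dict
    importances: dict[str, float] = field(default_factory=dict)
    feature_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.features].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X.reshape(1, -1) if X.ndim == 1 else X

    def predict(self, X) -> np.ndarray:
        """Ensemble-mean prediction, clipped to the [0, 1] response range."""
        return np.clip(self.ensemble.predict(self._matrix(X)), 0.0, 1.0)

    def predict_se(self, X) -> np.ndarray:
        """Standard error: per-tree prediction spread / sqrt(n_trees)."""
        M = self._matrix(X)
        per_tree = np.stack([t.predict(M) for t in self.ensemble.estimators_])
        return per_tree.std(axis=0, ddof=0) / np.sqrt(per_tree.shape[0])


DEFAULT_HYPERPARAMS = {"max_depth": 12, "max_features": None}


def _rf(Q_size: int, hyperparams: dict, seed: int, n_trees: int,
        oob: bool = False) -> RandomForestRegressor:
    mf = hyperparams.get("max_features")
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_depth=hyperparams.get("max_depth"),
        max_features=mf if mf else max(1, Q_size // 3),
        bootstrap=True, oob_score=oob, random_state=seed, n_jobs=1)


def tune_hyperparams(X, y, sample_weight, seed: int, n_search: int = 32,
                     n_trees: int = N_TREES) -> dict:
    """Seeded randomized search over tree depth and per-split feature
    count, scored on out-of-bag R^2."""
    rng = np.random.default_rng(seed)
    best, best_score = dict(DEFAULT_HYPERPARAMS), -np.inf
    n_feat = X.shape[1]
    for _ in range(n_search):
        hp = {"max_depth": int(rng.integers(3, 21)),
              "max_features": int(rng.integers(1, n_feat + 1))}
        rf = _rf(n_feat, hp, seed, n_trees, oob=True)
        rf.fit(X, y, sample_weight=sample_weight)
        score = rf.oob_score_
        if score > best_score:
            best, best_score = hp, score
    return best


def permutation_importance_scores(model: VulnerabilityModel, test: "BinnedSet",
                                  seed: int, n_repeats: int = 5) -> dict[str, float]:
    """Permutation importance (mean squared-error increase) on held-out bins."""
    rng = np.random.default_rng(seed)
    X = test.X[model.features].to_numpy(dtype=float)
    y = test.y
    base = np.mean((model.predict(X) - y) ** 2)
    scores = {}
    for k, name in enumerate(model.features):
        inc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, k] = rng.permutation(Xp[:, k])
            inc += np.mean((model.predict(Xp) - y) ** 2) - base
        scores[name] = inc / n_repeats
    return scores


def fit(train: BinnedSet, Q, seed: int, pft: str = "all",
        disturbance: str = "fire", n_trees: int = N_TREES,
        n_search: int = 32, hyperparams: dict | None = None,
        test: BinnedSet | None = None,
        importance: str = "permutation") -> VulnerabilityModel:
    """Fit the ensemble on (optionally PFT-restricted) training bins.

    For a PFT-specific model only bins where that PFT's renormalized cover
    fraction exceeds 5% are used, and sample weights are multiplied by the
    fraction. ``hyperparams`` skips the randomized search.
    """
    Q = list(Q)
    if not Q:
        raise ValueError("feature set Q must contain at least one feature")
    if len(train) == 0:
        raise InsufficientDataError("training set has no retained bins")
    bins = train.bins
    weights = bins["weight"].to_numpy(dtype=float)
    if pft != "all":
        if pft not in PFTS:
            raise ValueError(f"unknown PFT {pft!r}")
        frac = bins[f"pft_{pft}"].to_numpy(dtype=float)
        eligible = frac > PFT_MIN_FRACTION
        if eligible.sum() < 10:
            raise InsufficientDataError(
                f"only {int(eligible.sum())} bins with {pft} fraction > "
                f"{PFT_MIN_FRACTION}; need at least 10", pft=pft)
        bins = bins[eligible]
        weights = weights[eligible] * frac[eligible]
    X = bins[Q].to_numpy(dtype=float)
    y = bins["bl_rel"].to_numpy(dtype=float)

    if hyperparams is None:
        if n_search > 0 and len(bins) >= 10:
            hyperparams = tune_hyperparams(X, y, weights, seed,
                                           n_search=n_search, n_trees=n_trees)
        else:
            hyperparams = dict(DEFAULT_HYPERPARAMS)
    rf = _rf(len(Q), hyperparams, seed, n_trees)
    rf.fit(X, y, sample_weight=weights)

    model = VulnerabilityModel(
        disturbance=disturbance, pft=pft, features=Q, ensemble=rf,
        hyperparams=dict(hyperparams), seed=seed,
        feature_ranges={q: (float(bins[q].min()), float(bins[q].max()))
                        for q in Q})
    if importance == "impurity" or test is None:
        model.importances = dict(zip(Q, rf.feature_importances_))
    else:
        model.importances = permutation_importance_scores(model, test, seed)
    return model


# --------------------------------------------------------------------------
# feature selection


def spearman_prune(train: BinnedSet, importances: dict[str, float],
                   threshold: float = SPEARMAN_MAX) -> list[str]:
    """Drop the less important member of every pair with |rho| > threshold.

    Equal importances break the tie by dropping the lexicographically
    later name.
    """
    kept = sorted(importances, key=lambda n: (-importances[n], n))
    changed = True
    while changed:
        changed = False
        for a_i in range(len(kept)):
            for b_i in range(a_i + 1, len(kept)):
                a, b = kept[a_i], kept[b_i]
                xa, xb = train.bins[a], train.bins[b]
                rho = spearmanr(xa, xb).statistic
                if np.isnan(rho):
                    rho = 1.0 if xa.nunique() == 1 and xb.nunique() == 1 else 0.0
                if abs(rho) > threshold:
                    kept.remove(b)  # b is the less important of the pair
                    changed = True
                    break
            if changed:
                break
    return kept


def _test_r2(model: VulnerabilityModel, test: BinnedSet) -> float:
    y = test.y
    pred = model.predict(test.X)
    sst = np.sum((y - y.mean()) ** 2)
    return float(1 - np.sum((pred - y) ** 2) / sst) if sst > 0 else np.nan


def select_features(train: BinnedSet, test: BinnedSet, seed: int,
                    feature_cols=None, n_trees: int = N_TREES,
                    threshold: float = SPEARMAN_MAX) -> list[str]:
    """Two-stage selection: correlation pruning, then backward elimination
    keeping the subset with maximal test R^2 (ties -> smaller set)."""
    A = list(feature_cols or train.feature_cols)
    approx = fit(train, A, seed=seed, n_trees=n_trees, n_search=0, test=test)
    current = spearman_prune(train, approx.importances, threshold=threshold)

    path = []
    while current:
        model = fit(train, current, seed=seed, n_trees=n_trees, n_search=0,
                    test=test)
        path.append((list(current), _test_r2(model, test)))
        if len(current) == 1:
            break
        worst = min(current, key=lambda n: (model.importances[n], n))
        current = [c for c in current if c != worst]

    best_r2 = max(r2 for _, r2 in path)
    candidates = [q for q, r2 in path if r2 == best_r2]
    return min(candidates, key=len)


# --------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    r2: float
    rmse: float
    nrmse: float
    pbias: float  # percent
    re_per_bin: np.ndarray  # percent
    n_binned_records: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "nrmse": self.nrmse,
                "pbias": self.pbias, "n_binned_records": self.n_binned_records}


def validate(model: VulnerabilityModel, test: BinnedSet) -> ValidationReport:
    """Goodness-of-fit metrics on the held-out binned test set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    y = test.y
    pred = model.predict(test.X)
    err = pred - y
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sst = np.sum((y - y.mean()) ** 2)
    r2 = float(1 - np.sum(err ** 2) / sst) if sst > 0 else np.nan
    obs_range = float(y.max() - y.min())
    nrmse = rmse / obs_range if obs_range > 0 else np.nan
    total_obs = y.sum()
    pbias = float(100 * err.sum() / total_obs) if total_obs != 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        re = np.where(y != 0, 100 * err / y, np.nan)
    return ValidationReport(r2=r2, rmse=rmse, nrmse=nrmse, pbias=pbias,
                            re_per_bin=re, n_binned_records=test.n_records)
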