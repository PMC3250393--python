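"""Random-forest fusion models of songbird prevalence.

Per species, five regression forests are fit: one per sensor family
(radar, landsat, drl, lvis) and a fusion model on all 104 predictors.
Prevalence (0-9 detection-years) is modeled as a continuous response.
Accuracy is the out-of-bag (OOB) pseudo-r^2,

    pseudo_r2 = 1 - MSE(y, y_oob) / Var(y),

with population variance in the denominator; importance is the mean
increase in per-tree OOB MSE when a predictor's OOB values are permuted;
prediction intervals come from quantile regression forests (each tree's
co-leaf training responses form a weighted empirical conditional
distribution). Tree induction delegates to scikit-learn's
``DecisionTreeRegressor``; bootstrap bagging, OOB bookkeeping, pseudo-r^2,
permutation importance and the quantile machinery live here.

Defaults follow the analysis conventions of the randomForest R package:
800 trees, floor(p/3) candidate predictors per split, minimum node size 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .features import family_of, feature_columns
from .raster import Raster

MODEL_SUBSETS = ("radar", "landsat", "drl", "lvis", "fusion")


@dataclass
class ModelSpec:
    """Forest configuration for one model."""

    subset: str = "fusion"
    n_trees: int = 800
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset not in MODEL_SUBSETS:
            raise ValueError(f"subset must be one of {MODEL_SUBSETS}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def mtry(self, n_predictors: int) -> int:
        """Candidate predictors per split: floor(p/3), at least 1."""
        return max(1, n_predictors // 3)


def subset_features(table: pd.DataFrame, subset: str) -> pd.DataFrame:
    """The predictor columns belonging to one sensor family (or all)."""
    cols = feature_columns()
    if subset != "fusion":
        cols = [c for c in cols if family_of(c) == subset]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    return table[cols]


@dataclass
class FusionFit:
    """A fitted bagged forest with the bookkeeping needed downstream."""

    trees: list
    inbag_counts: np.ndarray  # (n_trees, n) bootstrap multiplicities
    X: np.ndarray  # (n, p) training predictors
    y: np.ndarray  # (n,) training response
    feature_names: list[str]
    oob_prediction: np.ndarray  # (n,)
    pseudo_r2: float
    spec: ModelSpec
    train_leaves: np.ndarray = field(default=None)  # (n_trees, n) leaf ids

    @property
    def oob_mask(self) -> np.ndarray:
        """(n_trees, n) boolean: observation out-of-bag for the tree."""
        return self.inbag_counts == 0


def fit_rf(features: pd.DataFrame, response, spec: ModelSpec | None = None) -> FusionFit:
    """Fit a bagged regression forest with explicit OOB bookkeeping.

    Each tree is grown on a with-replacement resample of size n with
    floor(p/3) candidate predictors per split. The OOB prediction for
    observation i averages the predictions of trees whose bootstrap sample
    omitted i; if any observation is never out of bag, extra trees are
    grown until every observation has OOB coverage.
    """
    spec = spec or ModelSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in predictors or response; exclude upstream")
    if n < 20:
        raise ValueError(f"need >= 20 observations, got {n}")
    rng = np.random.default_rng(spec.seed)
    mtry = spec.mtry(p)

    trees: list[DecisionTreeRegressor] = []
    inbag = []
    leaves = []

    def grow(n_new: int) -> None:
        for _ in range(n_new):
            idx = rng.integers(0, n, n)
            counts = np.bincount(idx, minlength=n)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=spec.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            trees.append(tree)
            inbag.append(counts)
            leaves.append(tree.apply(X))

    grow(spec.n_trees)
    # guarantee OOB coverage for every observation
    for _ in range(50):
        covered = (np.stack(inbag) == 0).any(axis=0)
        if covered.all():
            break
        grow(max(10, spec.n_trees // 10))
    else:
        raise RuntimeError("could not achieve OOB coverage for every observation")

    inbag_counts = np.stack(inbag)
    oob = inbag_counts == 0
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for t, tree in enumerate(trees):
        mask = oob[t]
        if mask.any():
            pred_sum[mask] += tree.predict(X[mask])
            pred_cnt[mask] += 1
    oob_prediction = pred_sum / pred_cnt

    return FusionFit(
        trees=trees,
        inbag_counts=inbag_counts,
        X=X,
        y=y,
        feature_names=list(features.columns),
        oob_prediction=oob_prediction,
        pseudo_r2=pseudo_r2(y, oob_prediction),
        spec=spec,
        train_leaves=np.stack(leaves),
    )


def pseudo_r2(observed, oob_predicted) -> float:
    """Variance explained on out-of-bag predictions: 1 - MSE / Var(y).

    Population variance (n denominator); may be negative when the forest
    predicts worse than the response mean.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(oob_predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("need equal-length 1-D vectors with n >= 2")
    var = y.var()
    if var == 0:
        raise ValueError("zero-variance response: pseudo-r2 undefined")
    mse = float(np.mean((y - yhat) ** 2))
    return 1.0 - mse / var


def variable_importance(fit: FusionFit, seed: int | None = None) -> pd.Series:
    """Permutation importance: increase in OOB MSE from permuting a predictor.

    Per tree, the predictor's values are permuted within that tree's OOB
    set; the importance of predictor j is the mean over trees of
    (permuted OOB MSE - baseline OOB MSE). Larger = more important.
    """
    rng = np.random.default_rng(fit.spec.seed + 1 if seed is None else seed)
    n_trees = len(fit.trees)
    p = fit.X.shape[1]
    deltas = np.zeros((n_trees, p))
    oob = fit.oob_mask
    for t, tree in enumerate(fit.trees):
        mask = oob[t]
        if not mask.any():
            continue
        X_oob = fit.X[mask]
        y_oob = fit.y[mask]
        base = np.mean((y_oob - tree.predict(X_oob)) ** 2)
        for j in range(p):
            perm = rng.permutation(len(y_oob))
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            deltas[t, j] = np.mean((y_oob - tree.predict(X_perm)) ** 2) - base
    return pd.Series(deltas.mean(axis=0), index=fit.feature_names)


def top10_frequency(importances: dict[str, pd.Series], k: int = 10) -> pd.Series:
    """How often each predictor ranks among the k most important variables
    across the per-species models (ties at rank k broken by the canonical
    column order)."""
    if not importances:
        raise ValueError("need at least one fitted model's importances")
    order = {name: i for i, name in enumerate(feature_columns())}
    counts: dict[str, int] = {}
    for imp in importances.values():
        ranked = sorted(
            imp.index, key=lambda c: (-imp[c], order.get(c, len(order)))
        )
        for name in ranked[:k]:
            counts[name] = counts.get(name, 0) + 1
    all_names = sorted(
        {n for imp in importances.values() for n in imp.index},
        key=lambda c: order.get(c, len(order)),
    )
    return pd.Series([counts.get(n, 0) for n in all_names], index=all_names)


def top10_family_frequency(importances: dict[str, pd.Series], k: int = 10) -> pd.Series:
    """Top-k counts aggregated by sensor family."""
    per_var = top10_frequency(importances, k)
    return per_var.groupby(per_var.index.map(family_of)).sum()


def predict_mean(fit: FusionFit, features) -> np.ndarray:
    """Mean-forest prediction for new rows (in-bag behavior on training rows)."""
    X = _validate_new(fit, features)
    out = np.zeros(len(X))
    for tree in fit.trees:
        out += tree.predict(X)
    return out / len(fit.trees)


def predict_quantiles(
    fit: FusionFit, features, quantiles=(0.1, 0.5, 0.9)
) -> np.ndarray:
    """Quantile-regression-forest conditional quantiles for new rows.

    Each training observation is weighted by its co-leaf frequency with
    the query row (equal weight per tree among the leaf's training
    occupants, averaged over trees); the returned quantiles are those of
    the resulting weighted empirical distribution of training responses
    (smallest y with cumulative weight >= q), non-decreasing in q.
    """
    q = np.asarray(quantiles, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    X = _validate_new(fit, features)
    n_train = len(fit.y)
    n_new = len(X)
    n_trees = len(fit.trees)

    W = np.zeros((n_new, n_train))
    for t, tree in enumerate(fit.trees):
        train_leaf = fit.train_leaves[t]
        new_leaf = tree.apply(X)
        leaf_ids, leaf_counts = np.unique(train_leaf, return_counts=True)
        count_of = dict(zip(leaf_ids, leaf_counts))
        # group training rows by leaf once per tree
        order = np.argsort(train_leaf, kind="stable")
        sorted_leaves = train_leaf[order]
        starts = np.searchsorted(sorted_leaves, leaf_ids)
        members = {
            lid: order[s : s + c] for lid, s, c in zip(leaf_ids, starts, leaf_counts)
        }
        for i, lid in enumerate(new_leaf):
            m = members.get(lid)
            if m is not None:
                W[i, m] += 1.0 / (count_of[lid] * n_trees)

    order = np.argsort(fit.y, kind="stable")
    y_sorted = fit.y[order]
    cum = np.cumsum(W[:, order], axis=1)
    total = cum[:, -1][:, None]
    out = np.empty((n_new, len(q)))
    for k, qk in enumerate(q):
        idx = (cum >= qk * total).argmax(axis=1)
        out[:, k] = y_sorted[idx]
    return out


def _validate_new(fit: FusionFit, features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in fit.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks model columns {missing}")
        features = features[fit.feature_names]
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(fit.feature_names):
        raise ValueError(
            f"expected {len(fit.feature_names)} predictor columns, got {X.shape}"
        )
    if np.isnan(X).any():
        raise ValueError("missing values in prediction features")
    return X


def predict_map(
    fit: FusionFit,
    landscape_features: pd.DataFrame,
    resolution: float = 88.8,
    clip: tuple[float, float] = (0.0, 9.0),
) -> Raster:
    """Mean-forest prevalence raster over landscape pixels.

    ``landscape_features`` must carry the model's predictor schema plus
    pixel-center ``x, y`` columns on a regular grid of the given
    resolution; predictions are clipped to the prevalence range for
    display.
    """
    pred = np.clip(predict_mean(fit, landscape_features), *clip)
    return _scatter_to_raster(landscape_features, pred, resolution)


def quantile_map(
    fit: FusionFit,
    landscape_features: pd.DataFrame,
    resolution: float = 88.8,
    quantiles=(0.1, 0.5, 0.9),
) -> dict[float, Raster]:
    """Per-pixel QRF quantile rasters (q10/q50/q90 prediction maps)."""
    preds = predict_quantiles(fit, landscape_features, quantiles)
    return {
        qk: _scatter_to_raster(landscape_features, preds[:, k], resolution)
        for k, qk in enumerate(quantiles)
    }


def _scatter_to_raster(features: pd.DataFrame, values, resolution) -> Raster:
    if "x" not in features.columns or "y" not in features.columns:
        raise ValueError("landscape features need pixel-center x, y columns")
    x = features["x"].to_numpy()
    y = features["y"].to_numpy()
    extent_x = x.max() + resolution / 2.0
    extent_y = y.max() + resolution / 2.0
    grid = Raster(
        np.full(
            (int(round(extent_y / resolution)), int(round(extent_x / resolution))),
            np.nan,
        ),
        resolution,
        origin=(0.0, extent_y),
    )
    row, col = grid.index_of(x, y)
    grid.values[row, col] = values
    return grid


def residual_correlogram(
    residuals,
    coordinates,
    lag_edges,
    n_permutations: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I correlogram of model residuals by distance band.

    Binary band weights (1 if lag_lo < d_ij <= lag_hi); significance by
    two-sided permutation of residuals over sites around the null
    expectation E[I] = -1/(n-1). Empty bands are reported as NaN.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    n = len(z)
    if n < 3 or len(xy) != n:
        raise ValueError("need >= 3 sites with matching coordinates")
    if z.var() == 0:
        raise ValueError("zero-variance residuals: Moran's I undefined")
    edges = np.asarray(lag_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two lag edges (one band)")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.nan)
    rng = np.random.default_rng(seed)
    expected = -1.0 / (n - 1)
    rows = []
    zc = z - z.mean()
    denom = (zc**2).sum()
    for lo, hi in zip(edges[:-1], edges[1:]):
        with np.errstate(invalid="ignore"):
            w = ((d > lo) & (d <= hi)).astype(float)
        s0 = w.sum()
        if s0 == 0:
            rows.append(
                {"lag_lo": lo, "lag_hi": hi, "moran_i": np.nan,
                 "p_value": np.nan, "n_pairs": 0}
            )
            continue
        def moran(v):
            vc = v - v.mean()
            return (n / s0) * (vc @ w @ vc) / (vc**2).sum()

        i_obs = (n / s0) * (zc @ w @ zc) / denom
        extreme = 1
        for _ in range(n_permutations):
            i_perm = moran(rng.permutation(z))
            if abs(i_perm - expected) >= abs(i_obs - expected):
                extreme += 1
        rows.append(
            {
                "lag_lo": lo,
                "lag_hi": hi,
                "moran_i": float(i_obs),
                "p_value": extreme / (n_permutations + 1),
                "n_pairs": int(s0),
            }
        )
    return pd.DataFrame(rows)


def oob_fraction_simulation(
    n: int = 369, n_resamples: int = 10_000, seed: int = 0
) -> float:
    """Mean fraction of observations absent from a bootstrap resample.

    Drawing n indices with replacement leaves each observation out with
    probability (1 - 1/n)^n -> e^-1, the classic ~37% out-of-bag share;
    this estimates it by direct simulation.
    """
    rng = np.random.default_rng(seed)
    frac = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.integers(0, n, n)
        frac[r] = 1.0 - len(np.unique(idx)) / n
    return float(frac.mean())
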