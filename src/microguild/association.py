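"""Random-Forest association of guild abundances with body weight.

The forest is a bagged ensemble of scikit-learn regression trees with the
R ``randomForest`` regression conventions: 500 trees, bootstrap resampling
of the samples, floor(p/3) candidate features per split, and out-of-bag
(OOB) bookkeeping kept explicitly per tree.  The first-party parts are the
leave-one-out CV, the rfcv-style backward feature elimination (importance
re-ranked inside every training fold, so the CV curve is leakage-free),
OOB permutation importance, and cross-dataset prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from scipy import stats as sps
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "RFParams",
    "Forest",
    "RFReport",
    "FittedModel",
    "rf_loocv",
    "importance_scores",
    "rfcv_select",
    "candidate_sizes",
    "fit_forest",
    "predict_external",
    "pearson_validation",
]


@dataclass(frozen=True)
class RFParams:
    """Forest hyperparameters (R randomForest regression defaults)."""

    n_trees: int = 500
    max_features: str | int = "third"  # floor(p/3), min 1

    def resolve_max_features(self, p: int) -> int:
        if self.max_features == "third":
            return max(1, p // 3)
        return max(1, int(self.max_features))


class Forest:
    """Bagged regression trees (bootstrap + random feature subsets).

    Deterministic given ``seed``.  Per-tree bootstrap and OOB index sets
    are stored so OOB permutation importance needs no refitting.
    """

    def __init__(self, params: RFParams, seed: int) -> None:
        self.params = params
        self.seed = int(seed) % (2 ** 31)
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_indices: list[np.ndarray] = []
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Forest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        n, p = X.shape
        mtry = self.params.resolve_max_features(p)
        rng = np.random.default_rng(self.seed)
        self.trees = []
        self.oob_indices = []
        self.n_features_ = p
        all_idx = np.arange(n)
        with sklearn.config_context(skip_parameter_validation=True):
            for _ in range(self.params.n_trees):
                boot = rng.integers(0, n, n)
                tree = DecisionTreeRegressor(
                    max_features=mtry,
                    random_state=int(rng.integers(2 ** 31)),
                )
                tree.fit(X[boot], y[boot], check_input=False)
                self.trees.append(tree)
                self.oob_indices.append(np.setdiff1d(all_idx, boot))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += tree.predict(X, check_input=False)
        return out / len(self.trees)

    def oob_permutation_importance(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Mean over trees of the increase in OOB squared error when one
        predictor's values are permuted (randomForest %IncMSE numerator)."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        p = X.shape[1]
        increases = np.zeros(p)
        n_used = np.zeros(p)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size < 2:
                continue
            Xo = X[oob]
            base = tree.predict(Xo, check_input=False)
            base_mse = np.mean((base - y[oob]) ** 2)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                perm = tree.predict(Xp, check_input=False)
                increases[j] += np.mean((perm - y[oob]) ** 2) - base_mse
                n_used[j] += 1
        n_used[n_used == 0] = 1
        return increases / n_used


@dataclass(frozen=True)
class FittedModel:
    """A trained forest plus the guild (column) order it expects."""

    forest: Forest
    feature_ids: tuple[str, ...]

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"guild(s) missing from new data: {missing}")
        pred = self.forest.predict(X.loc[:, list(self.feature_ids)].to_numpy())
        return pd.Series(pred, index=X.index, name="predicted")


@dataclass(frozen=True)
class RFReport:
    """Everything the association stage reports."""

    cv_curve: pd.Series  # index: predictor-set size, values: mean squared error
    k_star: int
    selected: tuple[str, ...]
    importances: pd.Series  # per guild, descending
    loo_predictions: pd.Series
    validation_r: float
    validation_p: float
    no_signal: bool
    seed: int
    params: RFParams = field(default_factory=RFParams)

    def __post_init__(self) -> None:
        if len(self.selected) != self.k_star:
            raise ValueError("selected set size must equal k_star")
        best = self.cv_curve.min()
        if self.cv_curve.loc[self.k_star] > best + 1e-9:
            raise ValueError("k_star must minimize the CV curve")


def _clean(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(y).astype(float).reindex(X.index)
    keep = y.notna()
    if keep.sum() < len(y):
        warnings.warn(
            f"{int((~keep).sum())} sample(s) without a body weight excluded",
            stacklevel=3,
        )
    X, y = X.loc[keep], y.loc[keep]
    if len(y) < 5:
        raise ValueError("need at least 5 samples with weights")
    return X, y


def rf_loocv(X: pd.DataFrame, y: pd.Series, params: RFParams | None = None,
             seed: int = 0) -> pd.Series:
    """Leave-one-out predictions: for each sample, train on the others and
    predict the held-out one.  Deterministic given ``seed``."""
    params = params or RFParams()
    X, y = _clean(X, y)
    Xa, ya = X.to_numpy(), y.to_numpy()
    preds = {}
    for i, sid in enumerate(X.index):
        train = np.arange(len(ya)) != i
        forest = Forest(params, seed + i).fit(Xa[train], ya[train])
        preds[sid] = float(forest.predict(Xa[i:i + 1])[0])
    return pd.Series(preds, name="predicted")


def importance_scores(X: pd.DataFrame, y: pd.Series,
                      params: RFParams | None = None, seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance per guild, sorted descending."""
    params = params or RFParams()
    X, y = _clean(X, y)
    forest = Forest(params, seed).fit(X.to_numpy(), y.to_numpy())
    rng = np.random.default_rng(seed)
    imp = forest.oob_permutation_importance(X.to_numpy(), y.to_numpy(), rng)
    return pd.Series(imp, index=X.columns, name="importance").sort_values(
        ascending=False, kind="stable"
    )


def candidate_sizes(p: int, step: float = 0.5) -> list[int]:
    """Halving sequence p, ceil(p*step), ..., 1 (distinct, decreasing)."""
    if not 0 < step < 1:
        raise ValueError("step must be in (0, 1)")
    sizes = [p]
    while sizes[-1] > 1:
        nxt = max(1, math.ceil(sizes[-1] * step))
        if nxt == sizes[-1]:
            nxt -= 1
        sizes.append(nxt)
    return sizes


def rfcv_select(X: pd.DataFrame, y: pd.Series, step: float = 0.5,
                params: RFParams | None = None, seed: int = 0) -> RFReport:
    """rfcv-style feature selection with leave-one-out CV.

    For every LOO fold, predictors are ranked by OOB permutation importance
    computed on the training fold only; for each candidate size the top-k
    training predictors are refit and the held-out sample predicted.  The
    selected size ``k*`` minimizes the CV mean squared error (ties go to
    the smaller set); the selected guilds are the top-``k*`` by importance
    from a full-data fit.
    """
    params = params or RFParams()
    X, y = _clean(X, y)
    n, p = X.shape
    sizes = candidate_sizes(p, step)
    Xa, ya = X.to_numpy(), y.to_numpy()

    sq_err = {k: [] for k in sizes}
    loo_full = {}
    for i in range(n):
        train = np.arange(n) != i
        fold_seed = (seed * 100003 + i) % (2 ** 31)
        forest = Forest(params, fold_seed).fit(Xa[train], ya[train])
        rng = np.random.default_rng(fold_seed)
        imp = forest.oob_permutation_importance(Xa[train], ya[train], rng)
        rank = np.argsort(-imp, kind="stable")
        for k in sizes:
            if k == p:
                # the full model is already fit on this fold
                pred = float(forest.predict(Xa[i:i + 1])[0])
                loo_full[X.index[i]] = pred
            else:
                cols = rank[:k]
                sub = Forest(params, fold_seed + 7919 * k).fit(
                    Xa[train][:, cols], ya[train])
                pred = float(sub.predict(Xa[i:i + 1, cols])[0])
            sq_err[k].append((pred - ya[i]) ** 2)

    curve = pd.Series({k: float(np.mean(v)) for k, v in sq_err.items()},
                      name="cv_mse").sort_index()
    best = curve.min()
    k_star = int(min(k for k in sizes if curve.loc[k] <= best + 1e-12))

    full_imp = importance_scores(X, y, params=params, seed=seed)
    selected = tuple(full_imp.index[:k_star])
    loo = pd.Series(loo_full, name="predicted").reindex(X.index)
    r, pval = pearson_validation(loo, y)
    return RFReport(
        cv_curve=curve, k_star=k_star, selected=selected,
        importances=full_imp, loo_predictions=loo,
        validation_r=r, validation_p=pval, no_signal=r <= 0,
        seed=seed, params=params,
    )


def fit_forest(X: pd.DataFrame, y: pd.Series, params: RFParams | None = None,
               seed: int = 0) -> FittedModel:
    """Fit one forest on the full dataset (for external prediction)."""
    params = params or RFParams()
    X, y = _clean(X, y)
    forest = Forest(params, seed).fit(X.to_numpy(), y.to_numpy())
    return FittedModel(forest=forest, feature_ids=tuple(X.columns))


def predict_external(model: FittedModel, X_new: pd.DataFrame) -> pd.Series:
    """Apply a trained forest to another dataset's guild abundances (no
    refitting); errors if any training guild is missing."""
    return model.predict(X_new)


def pearson_validation(predicted, measured) -> tuple[float, float]:
    """Pearson r of predicted vs measured, two-sided t-based p (n-2 df)."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.size != measured.size:
        raise ValueError("predicted and measured must align")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(measured) == 0:
        return 0.0, 1.0
    r, p = sps.pearsonr(predicted, measured)
    return float(r), float(p)
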