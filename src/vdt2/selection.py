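"""Train-set normalization and hybrid Lasso + RFE feature selection.

The selection strategy combines two complementary views: an L1-penalized
linear model of the 0/1 group label (classical Lasso; an L1-logistic
variant is available) keeps features with strong linear association, while
recursive feature elimination driven by a Random Forest's impurity
importances keeps features that contribute through nonlinear interactions.
The final feature set is the plain union of the two subsets, reported in
canonical column order.

Reference subsets reported for the VDT2 framework (a 12-name Lasso set, a
6-name RFE set, and their 13-name union) ship as constants for the worked
example.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, RFECV
from sklearn.linear_model import Lasso, LassoCV, LogisticRegressionCV

from .exceptions import VDT2Error, ZeroVarianceError
from .features import FEATURE_NAMES, canonical_feature_order

__all__ = [
    "Normalizer",
    "SelectionResult",
    "fit_normalizer",
    "lasso_select",
    "rfe_select",
    "union_select",
    "select_features",
    "REFERENCE_LASSO_SET",
    "REFERENCE_RFE_SET",
    "REFERENCE_UNION_SET",
]

#: Feature subsets reported for the VDT2 framework (worked-example fixture).
REFERENCE_LASSO_SET: tuple[str, ...] = (
    "stdevF0", "meanInten", "stdevInten", "HNR", "localShimmer",
    "localdbShimmer", "apq3Shimmer", "apq5Shimmer", "apq11Shimmer",
    "localJitter", "localabsJitter", "ppq5Jitter",
)
REFERENCE_RFE_SET: tuple[str, ...] = (
    "meanF0", "stdevF0", "meanInten", "stdevInten", "localdbShimmer",
    "ppq5Jitter",
)
REFERENCE_UNION_SET: tuple[str, ...] = (
    "meanF0", "stdevF0", "meanInten", "stdevInten", "HNR", "localShimmer",
    "localdbShimmer", "apq3Shimmer", "apq5Shimmer", "apq11Shimmer",
    "localJitter", "localabsJitter", "ppq5Jitter",
)


@dataclass
class Normalizer:
    """Z-scoring transform X -> (X - mu) / sigma fitted on training rows only.

    Applying a train-fitted normalizer to validation/test data deliberately
    does not re-centre it — the training mu/sigma are reused, preventing
    information leakage across the split.
    """

    mu: pd.Series
    sigma: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[list(self.mu.index)] = (table[self.mu.index] - self.mu) / self.sigma
        return out


def fit_normalizer(train: pd.DataFrame, features=FEATURE_NAMES) -> Normalizer:
    """Fit per-feature training mean and SD; zero-variance features error."""
    features = list(features)
    if train.empty:
        raise VDT2Error("cannot fit a normalizer on an empty table")
    mu = train[features].mean()
    sigma = train[features].std(ddof=0)
    dead = sigma[sigma == 0].index.tolist()
    if dead:
        raise ZeroVarianceError(
            f"zero training variance for feature(s) {dead}: z-score undefined"
        )
    return Normalizer(mu=mu, sigma=sigma)


@dataclass
class SelectionResult:
    """The two method subsets, their union, and per-feature diagnostics."""

    lasso_set: list[str]
    rfe_set: list[str]
    union_set: list[str]
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "lasso_set": self.lasso_set,
                    "rfe_set": self.rfe_set,
                    "union_set": self.union_set,
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
                sort_keys=True,
                ensure_ascii=False,
            )

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["lasso_set"], d["rfe_set"], d["union_set"], d.get("diagnostics", {}))


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise VDT2Error("need both classes present for selection")
    return y.astype(float)


def lasso_select(
    X: pd.DataFrame,
    y,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    method: str = "lasso",
    seed: int = 42,
) -> tuple[list[str], dict[str, float]]:
    """Sparse selection by an L1-penalized fit of the 0/1 label.

    The penalty is chosen by ``cv_folds``-fold cross-validation over
    ``lambda_grid`` (default 50 log-spaced values in [1e-4, 1]); features
    with nonzero coefficients are returned with their coefficients.
    ``method='logistic'`` swaps in L1-penalized logistic regression.
    """
    y = _check_xy(X, y)
    if lambda_grid is not None:
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if lambda_grid.size == 0:
            raise VDT2Error("lambda_grid must be nonempty")
    else:
        lambda_grid = np.logspace(-4, 0, 50)

    if method == "lasso":
        if lambda_grid.size == 1:
            model = Lasso(alpha=float(lambda_grid[0]), max_iter=50_000)
            model.fit(X, y)
        else:
            model = LassoCV(
                alphas=lambda_grid, cv=cv_folds, max_iter=50_000, random_state=seed
            )
            model.fit(X, y)
        coefs = model.coef_
    elif method == "logistic":
        model = LogisticRegressionCV(
            Cs=1.0 / lambda_grid,
            cv=cv_folds,
            penalty="l1",
            solver="liblinear",
            random_state=seed,
        )
        model.fit(X, y.astype(int))
        coefs = model.coef_.ravel()
    else:
        raise VDT2Error(f"unknown lasso method {method!r}")

    coef_map = dict(zip(X.columns, (float(c) for c in coefs)))
    selected = [f for f in X.columns if coef_map[f] != 0.0]
    return canonical_feature_order(selected), coef_map


def rfe_select(
    X: pd.DataFrame,
    y,
    k: int | None = 6,
    cv_folds: int = 5,
    n_trees: int = 200,
    seed: int = 42,
) -> tuple[list[str], dict[str, int]]:
    """Backward elimination with a Random Forest base estimator.

    One feature (the lowest impurity importance) is dropped per iteration
    until ``k`` remain; ``k=None`` chooses the size by cross-validation.
    Returns the retained names and the elimination ranking (1 = kept).
    """
    y = _check_xy(X, y)
    n = X.shape[1]
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    if k is None:
        selector = RFECV(forest, step=1, cv=cv_folds, min_features_to_select=1)
    else:
        if not 1 <= k <= n:
            raise VDT2Error(f"k must be in [1, {n}], got {k}")
        selector = RFE(forest, n_features_to_select=k, step=1)
    selector.fit(X, y.astype(int))
    ranking = dict(zip(X.columns, (int(r) for r in selector.ranking_)))
    selected = [f for f, keep in zip(X.columns, selector.support_) if keep]
    return canonical_feature_order(selected), ranking


def union_select(lasso_set, rfe_set) -> list[str]:
    """Union of the two subsets, in canonical feature order."""
    return canonical_feature_order(set(lasso_set) | set(rfe_set))


def select_features(
    X: pd.DataFrame,
    y,
    k: int | None = 6,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 42,
) -> SelectionResult:
    """Run both methods on normalized training data and fuse by union."""
    lasso_set, coefs = lasso_select(X, y, lambda_grid, cv_folds, seed=seed)
    rfe_set, ranking = rfe_select(X, y, k, cv_folds, seed=seed)
    return SelectionResult(
        lasso_set=lasso_set,
        rfe_set=rfe_set,
        union_set=union_select(lasso_set, rfe_set),
        diagnostics={"lasso_coef": coefs, "rfe_ranking": ranking},
    )
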