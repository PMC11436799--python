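"""Random-forest yield regressor and permutation importance.

The yield model is a random forest on the raw (unscaled) encoded predictors
with a floor on terminal-node size — at least 50 observations per leaf by
default — as the guard against over-fitting survey noise. The target is the
observed yield in t ha⁻¹, untransformed, so that every downstream quantity
(ICE curves, gap closures, Shapley values) is directly in t ha⁻¹.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import GridSearchCV

from .survey import FeatureMatrix, FeatureSchema


@dataclass(frozen=True)
class Hyperparams:
    n_trees: int = 500
    min_node_size: int = 50       # minimum observations in every terminal node
    mtry: int | None = None       # variables tried per split; default ⌈p/3⌉
    tune: bool = False            # small CV grid over node size and mtry


@dataclass
class YieldModel:
    """Fitted forest plus the metadata every downstream stage needs."""

    estimator: RandomForestRegressor
    features: tuple[str, ...]
    schema: FeatureSchema
    hyperparams: Hyperparams
    seed: int
    train_fingerprint: str
    feature_range: pd.DataFrame   # observed training min/max per feature
    oob_r2: float
    train_r2: float
    cv_r2: float | None = None

    def predict(self, matrix: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        frame = matrix.frame if isinstance(matrix, FeatureMatrix) else matrix
        missing = [c for c in self.features if c not in frame.columns]
        extra = [c for c in frame.columns if c not in self.features]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing={missing} unexpected={extra}"
            )
        X = frame[list(self.features)].to_numpy(float)
        out = self.estimator.predict(X)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite prediction")
        return out

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "YieldModel":
        return joblib.load(path)


@dataclass
class ImportanceRanking:
    """Features ordered by decreasing importance score."""

    frame: pd.DataFrame  # feature, importance, importance_sd
    method: str = "permutation"

    @property
    def features(self) -> list[str]:
        return self.frame["feature"].tolist()

    def restrict(self, features) -> "ImportanceRanking":
        """Restricted view, e.g. management variables only."""
        keep = self.frame["feature"].isin(list(features))
        return ImportanceRanking(self.frame.loc[keep].reset_index(drop=True), self.method)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


def fit_yield_model(
    matrix: FeatureMatrix,
    y: np.ndarray,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
) -> YieldModel:
    """Fit the forest; reproducible under a fixed seed.

    Out-of-bag R² is reported alongside the (optimistic) training R²; with
    ``hyperparams.tune`` a small cross-validated grid over node size
    {50, 100} and mtry is run first and ``cv_r2`` reports the best score.
    """
    hp = hyperparams or Hyperparams()
    y = np.asarray(y, float)
    X = matrix.to_numpy()
    n, p = X.shape
    if n < hp.min_node_size:
        raise ValueError(
            f"cannot satisfy min_node_size={hp.min_node_size} with only {n} records"
        )
    if n < 200:
        warnings.warn(f"fitting on only {n} records; estimates will be unstable")

    mtry = hp.mtry or max(1, math.ceil(p / 3))
    base = dict(
        n_estimators=hp.n_trees,
        min_samples_leaf=hp.min_node_size,
        max_features=min(mtry, p),
        random_state=seed,
        bootstrap=True,
        n_jobs=1,
    )
    cv_r2 = None
    if hp.tune:
        grid = {
            "min_samples_leaf": sorted({hp.min_node_size, 2 * hp.min_node_size}),
            "max_features": sorted({min(mtry, p), min(2 * mtry, p)}),
        }
        search = GridSearchCV(
            RandomForestRegressor(**{**base, "n_estimators": max(100, hp.n_trees // 5)}),
            grid,
            cv=3,
            scoring="r2",
        )
        search.fit(X, y)
        base["min_samples_leaf"] = search.best_params_["min_samples_leaf"]
        base["max_features"] = search.best_params_["max_features"]
        cv_r2 = float(search.best_score_)

    est = RandomForestRegressor(**base, oob_score=True)
    with warnings.catch_warnings():
        # constant-target fits legitimately yield an undefined OOB R²
        warnings.simplefilter("ignore")
        est.fit(X, y)
        oob = float(est.oob_score_) if np.var(y) > 0 else 1.0
    train_r2 = float(est.score(X, y)) if np.var(y) > 0 else 1.0

    return YieldModel(
        estimator=est,
        features=matrix.features,
        schema=matrix.schema,
        hyperparams=hp,
        seed=seed,
        train_fingerprint=_fingerprint(X, y),
        feature_range=matrix.feature_range.copy(),
        oob_r2=oob,
        train_r2=train_r2,
        cv_r2=cv_r2,
    )


def permutation_importance(
    model: YieldModel,
    matrix: FeatureMatrix,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    groups: list[list[str]] | None = None,
) -> ImportanceRanking:
    """Mean increase in squared prediction error when a feature is permuted.

    ``groups`` permutes sets of columns jointly (one score per group, keyed by
    the joined names) — the right tool when correlated or duplicated columns
    would otherwise share, and individually dilute, their importance. Ties are
    broken by feature name so the downstream top-2 selection is reproducible.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be ≥ 1")
    y = np.asarray(y, float)
    if groups is None:
        res = _sk_permutation_importance(
            model.estimator,
            matrix.frame[list(model.features)].to_numpy(float),
            y,
            n_repeats=n_repeats,
            random_state=seed,
            scoring="neg_mean_squared_error",
            n_jobs=1,
        )
        frame = pd.DataFrame(
            {
                "feature": list(model.features),
                "importance": res.importances_mean,
                "importance_sd": res.importances_std,
            }
        )
    else:
        rng = np.random.default_rng(seed)
        X = matrix.frame[list(model.features)].copy()
        base_mse = float(np.mean((model.estimator.predict(X.to_numpy(float)) - y) ** 2))
        rows = []
        for group in groups:
            scores = []
            for _ in range(n_repeats):
                perm = rng.permutation(len(X))
                Xp = X.copy()
                Xp.loc[:, group] = X.iloc[perm][group].to_numpy()
                mse = float(np.mean((model.estimator.predict(Xp.to_numpy(float)) - y) ** 2))
                scores.append(mse - base_mse)
            rows.append(
                {
                    "feature": "+".join(group),
                    "importance": float(np.mean(scores)),
                    "importance_sd": float(np.std(scores)),
                }
            )
        frame = pd.DataFrame(rows)

    frame = frame.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ImportanceRanking(frame)
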