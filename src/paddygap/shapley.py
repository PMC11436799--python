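"""Per-field Shapley attribution, constraint ranking, and co-limitation clusters.

The Shapley value φ_j of predictor j for one field is its marginal
contribution to that field's predicted yield, relative to the mean prediction
over a background population — in t ha⁻¹, so a negative φ for N fertilizer
reads directly as "the current N rate suppresses this field's predicted
yield". Attribution uses the interventional expectation: absent features are
replaced by background records, never by conditional draws, which makes
"deviation from the population mean prediction" literal and the additivity
identity base + Σφ = prediction exact.

Fields are then clustered by the signs of φ for irrigation (I) and nitrogen
(N): I⁻N⁻ fields are co-limited, I⁺N⁺ fields limited by neither; φ = 0 counts
as non-limiting (no expected gain from change).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._treeshap import forest_shap_interventional
from .model import YieldModel
from .survey import FeatureMatrix

#: Default number of background rows used for large tables (deterministic
#: seeded subsample); the full table is used when it is no larger than this.
DEFAULT_BACKGROUND_SIZE = 128

CLUSTER_LABELS = ("I+N+", "I-N+", "I-N-", "I+N-")


@dataclass
class ShapMatrix:
    """Per-field, per-feature attributions with their base value.

    ``base_value + values.sum(axis=1) == prediction`` holds for every record
    (up to float accumulation, well inside 1e-6 t ha⁻¹).
    """

    values: pd.DataFrame          # records × features, t ha⁻¹
    base_value: float             # mean prediction over the background, t ha⁻¹
    predictions: np.ndarray       # per-record model prediction, t ha⁻¹

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def additivity_error(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1).to_numpy() - self.predictions


def _background_matrix(
    matrix: FeatureMatrix, background: FeatureMatrix | None, size: int, seed: int
) -> np.ndarray:
    source = (background or matrix).frame
    X = source.to_numpy(float)
    if len(X) <= size:
        return X
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(X), size=size, replace=False))
    return X[idx]


def shap_values(
    model: YieldModel,
    matrix: FeatureMatrix,
    background: FeatureMatrix | None = None,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
) -> ShapMatrix:
    """Interventional Shapley values of the forest for every record.

    The background defaults to the explained matrix itself; tables larger
    than ``background_size`` are represented by a deterministic subsample
    (seeded from the model seed) to keep the exact pairwise tree traversal
    tractable. Deterministic given the model and inputs.
    """
    if tuple(matrix.features) != tuple(model.features):
        raise ValueError(
            f"feature schema mismatch: model={model.features} matrix={matrix.features}"
        )
    if background is not None and tuple(background.features) != tuple(model.features):
        raise ValueError("background schema does not match model schema")
    Z = _background_matrix(matrix, background, background_size, model.seed)
    phi = forest_shap_interventional(model.estimator, matrix.to_numpy(), Z)
    base = float(model.estimator.predict(Z).mean())
    preds = model.predict(matrix)
    return ShapMatrix(
        values=pd.DataFrame(phi, columns=list(model.features), index=matrix.frame.index),
        base_value=base,
        predictions=preds,
    )


def exact_shapley(
    model: YieldModel,
    record: pd.Series | pd.DataFrame,
    background: FeatureMatrix,
    max_features: int = 12,
) -> np.ndarray:
    """Shapley vector by exhaustive subset enumeration (test oracle).

    v(S) is the mean prediction over the background with the features outside
    S replaced by the background record's values; φ_j sums the weighted
    marginals over all subsets not containing j. Exponential in the number of
    features, hence refused beyond ``max_features``.
    """
    p = len(model.features)
    if p > max_features:
        raise ValueError(f"{p} features exceeds the exact-enumeration limit {max_features}")
    x = (
        record[list(model.features)].to_numpy(float).ravel()
        if isinstance(record, (pd.Series, pd.DataFrame))
        else np.asarray(record, float).ravel()
    )
    Z = background.frame[list(model.features)].to_numpy(float)
    m = len(Z)

    from math import factorial

    def value(subset: frozenset) -> float:
        hybrid = Z.copy()
        for j in subset:
            hybrid[:, j] = x[j]
        return float(model.estimator.predict(hybrid).mean())

    cache = {
        frozenset(s): value(frozenset(s))
        for r in range(p + 1)
        for s in combinations(range(p), r)
    }
    phi = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for s in combinations(others, r):
                phi[j] += w * (cache[frozenset(s) | {j}] - cache[frozenset(s)])
    return phi


def rank_importance(shap: ShapMatrix, group: list[str] | None = None) -> pd.DataFrame:
    """Mean absolute attribution per feature, descending; alphabetical ties.

    ``group`` restricts the ranking, e.g. to the management predictors for
    choosing intervention candidates.
    """
    if shap.values.empty:
        raise ValueError("empty attribution matrix")
    cols = list(group) if group is not None else list(shap.values.columns)
    scores = shap.values[cols].abs().mean(axis=0)
    out = (
        scores.rename("mean_abs_shap")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


@dataclass
class ClusterAssignment:
    """I±N± label per field plus share summaries."""

    labels: pd.Series              # per-field label, aligned to the shap index
    shares: pd.Series              # overall share per label, sums to 1
    district_shares: pd.DataFrame | None = None  # districts × labels


def assign_clusters(
    shap: ShapMatrix,
    var_irrigation: str = "irrigation_count",
    var_n: str = "n_rate",
    districts: pd.Series | None = None,
) -> ClusterAssignment:
    """Cluster fields by the sign of φ for irrigation and N.

    φ ≥ 0 maps to "+" (non-limiting): a zero marginal contribution implies no
    expected gain from changing the practice. Shares are reported overall and,
    when district labels are supplied, per district.
    """
    for var in (var_irrigation, var_n):
        if var not in shap.values.columns:
            raise ValueError(f"variable {var!r} not in attribution matrix")
    phi_i = shap.values[var_irrigation].to_numpy()
    phi_n = shap.values[var_n].to_numpy()
    labels = pd.Series(
        np.where(phi_i >= 0, "I+", "I-").astype(object)
        + np.where(phi_n >= 0, "N+", "N-"),
        index=shap.values.index,
        name="cluster",
    )
    shares = (
        labels.value_counts(normalize=True)
        .reindex(CLUSTER_LABELS, fill_value=0.0)
        .rename("share")
    )
    district_shares = None
    if districts is not None:
        district_shares = (
            pd.crosstab(np.asarray(districts), labels, normalize="index")
            .reindex(columns=CLUSTER_LABELS, fill_value=0.0)
            .rename_axis(index="district")
        )
    return ClusterAssignment(labels, shares, district_shares)
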