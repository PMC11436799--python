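"""Shared fixtures: small synthetic landscapes and fitted models.

Heavy objects are session-scoped so the suite fits in a modest time budget;
tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paddygap.model import Hyperparams, YieldModel, fit_yield_model
from paddygap.survey import FeatureMatrix, FeatureSchema, encode_features
from paddygap.synthetic import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_fields=600, n_districts=6, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_survey(small_config)


@pytest.fixture(scope="session")
def small_table(small_landscape):
    return small_landscape[0]


@pytest.fixture(scope="session")
def small_truth(small_landscape):
    return small_landscape[1]


@pytest.fixture(scope="session")
def small_matrix(small_table) -> FeatureMatrix:
    return encode_features(small_table)


@pytest.fixture(scope="session")
def small_model(small_matrix, small_table) -> YieldModel:
    return fit_yield_model(
        small_matrix, small_table.yields, Hyperparams(n_trees=150), seed=12
    )


def make_stub_model(predict_fn, features, categorical_levels=None) -> YieldModel:
    """YieldModel wrapping an arbitrary prediction function (for oracles)."""

    class _Stub:
        def predict(self, X):
            return np.asarray(predict_fn(np.asarray(X, float)), float)

    frame = pd.DataFrame(np.zeros((2, len(features))), columns=list(features))
    schema = FeatureSchema(
        management=tuple(features),
        biophysical=(),
        categorical_levels=categorical_levels or {},
    )
    return YieldModel(
        estimator=_Stub(),
        features=tuple(features),
        schema=schema,
        hyperparams=Hyperparams(n_trees=1, min_node_size=1),
        seed=0,
        train_fingerprint="stub",
        feature_range=pd.DataFrame(
            {c: [0.0, 1.0] for c in features}, index=["min", "max"]
        ),
        oob_r2=float("nan"),
        train_r2=float("nan"),
    )
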