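"""Attainable yield, ICE sweeps, and the sequential two-constraint decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddygap.decomposition import (
    attainable_yield,
    decompose_sequential,
    ice_sweep,
)
from paddygap.model import Hyperparams, ImportanceRanking, fit_yield_model, permutation_importance
from paddygap.survey import SurveyTable, encode_features
from paddygap.synthetic import GeneratorConfig, generate_survey

from tests.conftest import make_stub_model


def _table_with_yields(y):
    n = len(y)
    frame = pd.DataFrame(
        {
            "field_id": [f"F{i}" for i in range(n)],
            "lat": 26.0,
            "lon": 85.0,
            "state": "S",
            "district": "d",
            "year": 2018,
            "yield_obs": y,
            "n_rate": 100.0,
            "p_rate": 20.0,
            "k_rate": 20.0,
            "zn_rate": 2.0,
            "irrigation_count": 3,
            "sowing_doy": 170,
            "variety_class": "short",
            "weather_srad": 2000.0,
            "weather_tmax": 32.0,
        }
    )
    return SurveyTable(frame)


class TestAttainableYield:
    def test_integer_ladder(self):
        gaps = attainable_yield(_table_with_yields(np.arange(1.0, 11.0)))
        assert gaps.y_att == 10.0
        assert sorted(gaps.gaps) == list(range(1, 10))

    def test_all_equal_yields(self):
        gaps = attainable_yield(_table_with_yields(np.full(12, 3.5)))
        assert gaps.y_att == 3.5
        assert (gaps.gaps == 0).all()

    def test_matches_sort_and_mean_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(1, 8, size=20)
        gaps = attainable_yield(_table_with_yields(y), decile=0.10)
        top2 = np.sort(y)[-2:]
        assert gaps.y_att == pytest.approx(top2.mean(), abs=0)

    @settings(deadline=None, max_examples=50)
    @given(
        y=st.lists(
            st.floats(min_value=0.5, max_value=14.0, allow_nan=False),
            min_size=10,
            max_size=60,
        )
    )
    def test_oracle_equivalence_property(self, y):
        y = np.asarray(y)
        gaps = attainable_yield(_table_with_yields(y))
        cutoff = np.quantile(y, 0.9)
        oracle = y[y >= cutoff].mean()
        assert gaps.y_att == oracle
        assert (gaps.gaps > 0).all() or np.isclose(gaps.gaps, 0).all()

    def test_empty_and_tiny_tables_rejected(self):
        with pytest.raises(ValueError):
            attainable_yield(_table_with_yields(np.array([4.0] * 5)))


class TestIceSweep:
    def test_flat_curve_argmax_is_reported_value(self):
        model = make_stub_model(lambda X: np.full(len(X), 5.0), ["n_rate", "p_rate"])
        model.feature_range.loc[:, "n_rate"] = [0.0, 200.0]
        rec = pd.Series({"n_rate": 73.0, "p_rate": 10.0})
        curve = ice_sweep(model, rec, "n_rate", grid_step=10.0)
        assert curve.argmax == 73.0
        assert curve.maximum == curve.reported_prediction == 5.0

    def test_unknown_variable_raises(self, small_model, small_matrix):
        with pytest.raises(ValueError, match="not in model schema"):
            ice_sweep(small_model, small_matrix.frame.iloc[0], "soil_ph")

    def test_grid_covers_observed_range_and_reported_value(self, small_model, small_matrix):
        rec = small_matrix.frame.iloc[3]
        curve = ice_sweep(small_model, rec, "n_rate", grid_step=10.0)
        lo = small_model.feature_range.loc["min", "n_rate"]
        hi = small_model.feature_range.loc["max", "n_rate"]
        assert curve.grid.min() == lo and curve.grid.max() == hi
        assert rec["n_rate"] in curve.grid

    def test_argmax_matches_brute_force_grid(self, small_model, small_matrix):
        rec = small_matrix.frame.iloc[10]
        curve = ice_sweep(small_model, rec, "n_rate", grid_step=10.0)
        # brute force: one prediction per grid point
        brute = []
        for v in curve.grid:
            row = rec.copy()
            row["n_rate"] = v
            brute.append(small_model.predict(pd.DataFrame([row]))[0])
        brute = np.asarray(brute)
        np.testing.assert_allclose(curve.predictions, brute)
        assert curve.maximum == brute.max()

    def test_resweep_at_argmax_gives_zero_gap(self, small_model, small_matrix):
        rec = small_matrix.frame.iloc[5].copy()
        first = ice_sweep(small_model, rec, "n_rate", grid_step=10.0)
        rec["n_rate"] = first.argmax
        second = ice_sweep(small_model, rec, "n_rate", grid_step=10.0)
        assert second.argmax == rec["n_rate"]
        assert second.maximum - second.reported_prediction == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def zero_noise_setup():
    cfg = GeneratorConfig(n_fields=2500, n_districts=6, noise_sd=0.0, seed=30)
    table, truth = generate_survey(cfg)
    matrix = encode_features(table)
    model = fit_yield_model(matrix, table.yields, Hyperparams(n_trees=150), seed=31)
    ranking = permutation_importance(model, matrix, table.yields, seed=32).restrict(
        table.schema.management
    )
    return cfg, table, truth, matrix, model, ranking


class TestSequentialDecomposition:
    def test_gap_closures_nonnegative_and_additive(self, zero_noise_setup):
        _, _, _, matrix, model, ranking = zero_noise_setup
        res = decompose_sequential(model, matrix, ranking)
        assert (res.frame["yg1"] >= 0).all()
        assert (res.frame["yg2"] >= 0).all()
        np.testing.assert_allclose(
            res.frame["combined"], res.frame["yg1"] + res.frame["yg2"], atol=1e-12
        )

    def test_constant_model_gives_zero_gaps(self, small_matrix):
        model = make_stub_model(
            lambda X: np.full(len(X), 4.0), list(small_matrix.features)
        )
        model.feature_range.loc[:, :] = small_matrix.feature_range.loc[:, :].to_numpy()
        ranking = ImportanceRanking(
            pd.DataFrame(
                {"feature": ["n_rate", "irrigation_count"], "importance": [1.0, 0.5],
                 "importance_sd": [0.0, 0.0]}
            )
        )
        res = decompose_sequential(model, small_matrix, ranking)
        assert (res.frame["yg1"] == 0).all() and (res.frame["yg2"] == 0).all()
        assert (res.frame["n_rate_opt"] == small_matrix.frame["n_rate"]).all()

    def test_matches_closed_form_increments_on_additive_truth(self, zero_noise_setup):
        cfg, table, truth, matrix, model, ranking = zero_noise_setup
        res = decompose_sequential(model, matrix, ranking)
        r = cfg.response_params

        def g_n(n):
            return r.n_max_gain * (1 - np.exp(-np.minimum(n, r.n_plateau) / r.n_scale))

        n_obs = table.frame["n_rate"].to_numpy()
        oracle = g_n(min(n_obs.max(), r.n_plateau)) - g_n(n_obs)
        ygn = res.frame["yg1" if res.variables[0] == "n_rate" else "yg2"].to_numpy()
        model_rmse = np.sqrt(
            np.mean((model.predict(matrix) - truth.frame["true_yield"].to_numpy()) ** 2)
        )
        assert np.mean(np.abs(ygn - oracle)) <= 2 * model_rmse
        assert np.corrcoef(ygn, oracle)[0, 1] > 0.9

    def test_order_swap_changes_combined_by_under_ten_percent(self, zero_noise_setup):
        _, _, _, matrix, model, ranking = zero_noise_setup
        forward = decompose_sequential(model, matrix, ranking)
        swapped = ImportanceRanking(
            ranking.frame.iloc[[1, 0] + list(range(2, len(ranking.frame)))].reset_index(
                drop=True
            )
        )
        backward = decompose_sequential(model, matrix, swapped)
        c1 = forward.frame["combined"].mean()
        c2 = backward.frame["combined"].mean()
        assert abs(c1 - c2) / c1 < 0.10

    def test_fewer_than_two_variables_rejected(self, small_model, small_matrix):
        one = ImportanceRanking(
            pd.DataFrame({"feature": ["n_rate"], "importance": [1.0], "importance_sd": [0.0]})
        )
        with pytest.raises(ValueError, match="2"):
            decompose_sequential(small_model, small_matrix, one)

    def test_relative_expression_uses_state_attainable(self, zero_noise_setup):
        _, table, _, matrix, model, ranking = zero_noise_setup
        y_att = attainable_yield(table).y_att
        res = decompose_sequential(model, matrix, ranking, y_att=y_att)
        rel = res.relative()
        np.testing.assert_allclose(rel["yg1"], res.frame["yg1"] / y_att)
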