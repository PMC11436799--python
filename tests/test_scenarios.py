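"""Scenario engine: targeting rules, accounting identities, aggregation."""

import numpy as np
import pandas as pd
import pytest

from paddygap.model import Hyperparams, fit_yield_model
from paddygap.scenarios import (
    Prices,
    ScenarioSpec,
    apply_scenario,
    derive_blanket_rate,
    evaluate_scenario,
)
from paddygap.shapley import assign_clusters, shap_values
from paddygap.survey import SurveyTable, encode_features
from paddygap.synthetic import generate_district_areas

from tests.conftest import make_stub_model


@pytest.fixture(scope="module")
def scenario_setup(small_table, small_matrix, small_model, small_config):
    shap = shap_values(small_model, small_matrix, background_size=64)
    clusters = assign_clusters(shap, districts=small_table.frame["district"])
    areas = generate_district_areas(small_config).set_index("district")["rice_area_ha"]
    return shap, clusters, areas


def test_blanket_scenario_sets_every_field_to_the_rate(small_table):
    spec = ScenarioSpec.preset(2)
    modified, mask = apply_scenario(small_table, spec)
    assert (modified.frame["n_rate"] == 180.0).all()
    # fields already at 180 would be unchanged; none are in this landscape
    assert mask.sum() == len(small_table)


def test_blanket_rate_adjusts_down_as_well_as_up(small_table):
    spec = ScenarioSpec.preset(1)  # 125 kg N ha⁻¹
    over = small_table.frame["n_rate"] > 125.0
    assert over.any()
    modified, _ = apply_scenario(small_table, spec)
    assert (modified.frame["n_rate"] == 125.0).all()


def test_targeted_scenario_changes_exactly_the_negative_shap_fields(
    small_table, scenario_setup
):
    shap, clusters, _ = scenario_setup
    spec = ScenarioSpec.preset(3)
    modified, mask = apply_scenario(small_table, spec, clusters=clusters)
    phi_n = shap.values["n_rate"].to_numpy()
    below_rate = small_table.frame["n_rate"].to_numpy() < 180.0
    np.testing.assert_array_equal(mask, (phi_n < 0) & below_rate)
    # in this landscape every N-limited field sits below the new rate,
    # so the change mask is exactly the SHAP sign test
    assert below_rate[phi_n < 0].all()
    np.testing.assert_array_equal(mask, phi_n < 0)
    untouched = ~mask
    np.testing.assert_array_equal(
        modified.frame.loc[untouched, "n_rate"],
        small_table.frame.loc[untouched, "n_rate"],
    )


def test_targeted_scenarios_never_lower_inputs(small_table, scenario_setup):
    _, clusters, _ = scenario_setup
    modified, _ = apply_scenario(small_table, ScenarioSpec.preset(4), clusters=clusters)
    assert (modified.frame["n_rate"] >= small_table.frame["n_rate"] - 1e-12).all()
    assert (
        modified.frame["irrigation_count"] >= small_table.frame["irrigation_count"]
    ).all()


def test_scenario4_targets_subset_of_scenario3(small_table, scenario_setup):
    _, clusters, _ = scenario_setup
    _, mask3 = apply_scenario(small_table, ScenarioSpec.preset(3), clusters=clusters)
    _, mask4 = apply_scenario(small_table, ScenarioSpec.preset(4), clusters=clusters)
    assert (mask4 & ~mask3).sum() == 0


def test_targeted_scenario_without_clusters_raises(small_table):
    with pytest.raises(ValueError, match="cluster"):
        apply_scenario(small_table, ScenarioSpec.preset(3))


def test_no_colimited_fields_means_no_changes(small_table):
    labels = pd.Series(["I+N+"] * len(small_table), name="cluster")
    from paddygap.shapley import CLUSTER_LABELS, ClusterAssignment

    clusters = ClusterAssignment(
        labels, labels.value_counts(normalize=True).reindex(CLUSTER_LABELS, fill_value=0.0)
    )
    modified, mask = apply_scenario(small_table, ScenarioSpec.preset(4), clusters=clusters)
    assert mask.sum() == 0
    pd.testing.assert_frame_equal(modified.frame, small_table.frame)


def _one_field_table(n_rate=60.0, irrigation=3):
    frame = pd.DataFrame(
        {
            "field_id": ["F1"],
            "lat": [26.0],
            "lon": [85.0],
            "state": ["S"],
            "district": ["d1"],
            "year": [2018],
            "yield_obs": [4.0],
            "n_rate": [n_rate],
            "p_rate": [20.0],
            "k_rate": [20.0],
            "zn_rate": [2.0],
            "irrigation_count": [irrigation],
            "sowing_doy": [170],
            "variety_class": ["short"],
            "weather_srad": [2000.0],
            "weather_tmax": [32.0],
        }
    )
    return SurveyTable(frame)


def test_profit_identity_hand_arithmetic():
    """0.5 t × 250 USD − 60 kg × 0.14 − 2 × 20 USD = 76.6 USD per hectare."""
    baseline = _one_field_table(n_rate=60.0, irrigation=3)
    modified = _one_field_table(n_rate=120.0, irrigation=5)
    features = encode_features(baseline).features
    n_idx = features.index("n_rate")
    model = make_stub_model(
        lambda X: np.where(X[:, n_idx] > 100, 4.5, 4.0), features,
        categorical_levels={"variety_class": ("short", "medium", "long")},
    )
    spec = ScenarioSpec.preset(
        4, prices=Prices(irrigation_usd=20.0, n_usd_per_kg=0.14, paddy_usd_per_t=250.0)
    )
    areas = pd.Series({"d1": 1.0}, name="rice_area_ha")
    result = evaluate_scenario(model, baseline, modified, areas, spec)
    assert result.totals["mean_d_profit_adopters_usd_ha"] == pytest.approx(76.6)
    assert result.totals["mean_d_yield_adopters_t_ha"] == pytest.approx(0.5)
    assert result.totals["nue_kg_grain_per_kg_n"] == pytest.approx(500.0 / 60.0)


def test_unmodified_table_gives_zero_deltas_and_undefined_nue(small_table, small_model, scenario_setup):
    _, _, areas = scenario_setup
    spec = ScenarioSpec.preset(2)
    result = evaluate_scenario(small_model, small_table, small_table, areas, spec)
    assert result.totals["d_production_t"] == 0.0
    assert result.totals["d_n_use_t"] == 0.0
    assert np.isnan(result.totals["nue_kg_grain_per_kg_n"])


def test_missing_district_area_raises(small_table, small_model, scenario_setup):
    _, clusters, areas = scenario_setup
    spec = ScenarioSpec.preset(2)
    modified, mask = apply_scenario(small_table, spec)
    with pytest.raises(ValueError, match="missing"):
        evaluate_scenario(
            small_model, small_table, modified, areas.drop(areas.index[0]), spec, mask
        )


def test_district_deltas_sum_to_totals(small_table, small_model, scenario_setup):
    _, clusters, areas = scenario_setup
    spec = ScenarioSpec.preset(
        3, prices=Prices(paddy_usd_per_t=250.0)
    )
    modified, mask = apply_scenario(small_table, spec, clusters=clusters)
    result = evaluate_scenario(small_model, small_table, modified, areas, spec, mask)
    for col, total in (
        ("d_production_t", "d_production_t"),
        ("d_n_use_t", "d_n_use_t"),
        ("d_profit_usd", "d_profit_usd"),
    ):
        assert result.districts[col].sum() == pytest.approx(result.totals[total])
    assert (result.districts.loc[result.districts["fraction_changed"] == 0,
                                 "d_production_t"] == 0).all()


def test_targeting_beats_blanket_on_mean_adopter_gain(
    small_table, small_model, scenario_setup
):
    _, clusters, areas = scenario_setup
    blanket, mask2 = apply_scenario(small_table, ScenarioSpec.preset(2))
    targeted, mask3 = apply_scenario(
        small_table, ScenarioSpec.preset(3), clusters=clusters
    )
    r2 = evaluate_scenario(
        small_model, small_table, blanket, areas, ScenarioSpec.preset(2), mask2
    )
    r3 = evaluate_scenario(
        small_model, small_table, targeted, areas, ScenarioSpec.preset(3), mask3
    )
    assert (
        r3.totals["mean_d_yield_adopters_t_ha"]
        >= r2.totals["mean_d_yield_adopters_t_ha"]
    )


def test_derived_blanket_rate_is_plausible(small_model, small_matrix):
    rate = derive_blanket_rate(small_model, small_matrix, "n_rate", grid_step=10.0)
    lo = small_model.feature_range.loc["min", "n_rate"]
    hi = small_model.feature_range.loc["max", "n_rate"]
    assert lo <= rate <= hi
    assert rate > small_matrix.frame["n_rate"].median()


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ScenarioSpec(scenario_id=1, n_rate_new=-5.0)
    with pytest.raises(ValueError):
        ScenarioSpec(scenario_id=1, n_rate_new=100.0, targeting="everything")
    with pytest.raises(ValueError):
        Prices(irrigation_usd=-1.0)
    with pytest.raises(ValueError):
        ScenarioSpec.preset(9)
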