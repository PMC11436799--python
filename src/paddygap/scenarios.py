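"""Ex-ante intensification scenarios: blanket versus targeted practice change.

Four counterfactuals are evaluated against current farmer practice:

1. blanket adoption of the state N recommendation (125 kg N ha⁻¹, all fields);
2. blanket adoption of an analytics-derived N rate (180 kg N ha⁻¹, all fields);
3. the 180 kg N ha⁻¹ rate targeted only at fields whose N Shapley value is
   negative (the I⁺N⁻ and I⁻N⁻ clusters);
4. joint N and irrigation change (180 kg N ha⁻¹ and 5 irrigations) targeted
   only at co-limited I⁻N⁻ fields.

Blanket scenarios impose the rate up *and* down (over-fertilized fields are
brought back to the recommendation); targeted scenarios only ever raise
inputs. Counterfactual yields come from the fitted model; deltas are
aggregated to district level through each district's rice area, and partial
net returns price the extra yield at the paddy support price minus the costs
of extra N and irrigation events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import YieldModel
from .shapley import ClusterAssignment
from .survey import SurveyTable, encode_features

#: kg grain per t of paddy
_KG_PER_T = 1000.0


@dataclass(frozen=True)
class Prices:
    irrigation_usd: float = 20.0     # USD per irrigation event
    n_usd_per_kg: float = 0.14       # USD per kg N (subsidized)
    paddy_usd_per_t: float | None = None  # from the rice minimum support price

    def __post_init__(self) -> None:
        if self.irrigation_usd < 0 or self.n_usd_per_kg < 0:
            raise ValueError("prices must be non-negative")
        if self.paddy_usd_per_t is not None and self.paddy_usd_per_t < 0:
            raise ValueError("prices must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: int
    n_rate_new: float
    irrigation_new: int | None = None
    #: "all" | "n_limited" (φ_N < 0) | "co_limited" (φ_N < 0 and φ_I < 0)
    targeting: str = "all"
    prices: Prices = field(default_factory=Prices)

    def __post_init__(self) -> None:
        if self.n_rate_new < 0:
            raise ValueError("n_rate_new must be ≥ 0")
        if self.targeting not in ("all", "n_limited", "co_limited"):
            raise ValueError(f"unknown targeting rule {self.targeting!r}")

    @staticmethod
    def preset(scenario_id: int, prices: Prices | None = None) -> "ScenarioSpec":
        """The four canonical scenarios."""
        prices = prices or Prices()
        presets = {
            1: dict(n_rate_new=125.0, targeting="all"),
            2: dict(n_rate_new=180.0, targeting="all"),
            3: dict(n_rate_new=180.0, targeting="n_limited"),
            4: dict(n_rate_new=180.0, irrigation_new=5, targeting="co_limited"),
        }
        if scenario_id not in presets:
            raise ValueError(f"scenario_id must be 1..4, got {scenario_id}")
        return ScenarioSpec(scenario_id=scenario_id, prices=prices, **presets[scenario_id])


def apply_scenario(
    table: SurveyTable,
    spec: ScenarioSpec,
    clusters: ClusterAssignment | None = None,
) -> tuple[SurveyTable, np.ndarray]:
    """Modified survey table plus the boolean mask of fields actually changed.

    Targeted rules require cluster labels computed on the same table. In
    blanket scenarios every field is set to the scenario N rate (down-adjusting
    over-users); in targeted scenarios inputs are only raised, so a targeted
    field already at or above the rate is left unchanged.
    """
    frame = table.frame.copy()
    if spec.targeting == "all":
        targeted = np.ones(len(frame), dtype=bool)
    else:
        if clusters is None:
            raise ValueError(
                f"scenario {spec.scenario_id} targets clusters; cluster labels required"
            )
        labels = clusters.labels.to_numpy()
        if len(labels) != len(frame):
            raise ValueError("cluster labels do not align with the survey table")
        if spec.targeting == "n_limited":
            targeted = np.char.endswith(labels.astype(str), "N-")
        else:  # co_limited
            targeted = labels == "I-N-"

    new_n = frame["n_rate"].to_numpy(float).copy()
    if spec.targeting == "all":
        new_n[targeted] = spec.n_rate_new
    else:
        new_n[targeted] = np.maximum(new_n[targeted], spec.n_rate_new)
    new_irr = frame["irrigation_count"].to_numpy(int).copy()
    if spec.irrigation_new is not None:
        new_irr[targeted] = np.maximum(new_irr[targeted], spec.irrigation_new)

    changed = targeted & (
        (new_n != frame["n_rate"].to_numpy(float))
        | (new_irr != frame["irrigation_count"].to_numpy(int))
    )
    frame["n_rate"] = new_n
    frame["irrigation_count"] = new_irr
    return SurveyTable(frame, schema=table.schema, state=table.state), changed


@dataclass
class ScenarioResult:
    """District-level and total deltas of one scenario against baseline."""

    districts: pd.DataFrame   # per-district deltas
    totals: pd.Series         # region totals / means
    spec: ScenarioSpec


def evaluate_scenario(
    model: YieldModel,
    baseline: SurveyTable,
    modified: SurveyTable,
    district_areas: pd.Series,
    spec: ScenarioSpec,
    mask: np.ndarray | None = None,
) -> ScenarioResult:
    """Predict counterfactual yields and aggregate deltas to district level.

    District production delta = (mean per-field yield delta among surveyed
    fields, non-adopters contributing zero) × district rice area; the same
    per-hectare scaling is used for N (kg → t) and irrigation events (one
    surveyed field standing for one hectare). NUE of the additional N is
    kg grain per kg N over the fields receiving extra N, reported as NaN when
    no field does. Per-adopting-field means are over the change mask only.
    """
    base_frame = baseline.frame
    if not base_frame["field_id"].equals(modified.frame["field_id"]):
        raise ValueError("baseline and modified tables must hold the same fields")
    missing = set(base_frame["district"]) - set(district_areas.index)
    if missing:
        raise ValueError(f"district areas missing for: {sorted(missing)}")

    enc = encode_features(baseline)
    d_yield = model.predict(encode_features(modified, enc.encoding)) - model.predict(enc)
    d_n = modified.frame["n_rate"].to_numpy(float) - base_frame["n_rate"].to_numpy(float)
    d_irr = (
        modified.frame["irrigation_count"].to_numpy(float)
        - base_frame["irrigation_count"].to_numpy(float)
    )
    if mask is None:
        mask = (d_n != 0) | (d_irr != 0)
    # untargeted fields are identical in both tables, hence zero deltas
    d_profit = np.zeros_like(d_yield)
    price = spec.prices.paddy_usd_per_t
    if price is not None:
        d_profit = (
            d_yield * price
            - d_n * spec.prices.n_usd_per_kg
            - d_irr * spec.prices.irrigation_usd
        )

    per_field = pd.DataFrame(
        {
            "district": base_frame["district"].to_numpy(),
            "d_yield": d_yield,
            "d_n": d_n,
            "d_irr": d_irr,
            "d_profit": d_profit,
            "changed": mask,
        }
    )
    grouped = per_field.groupby("district", observed=True)
    area = district_areas.reindex(grouped.size().index)
    districts = pd.DataFrame(
        {
            "rice_area_ha": area,
            "d_production_t": grouped["d_yield"].mean() * area,
            "d_n_use_t": grouped["d_n"].mean() * area / _KG_PER_T,
            "d_irrigation_events": grouped["d_irr"].mean() * area,
            "fraction_changed": grouped["changed"].mean(),
            "d_profit_usd": grouped["d_profit"].mean() * area,
        }
    )
    adopters = per_field[per_field["changed"]]
    extra_n = per_field["d_n"] > 0
    nue = (
        float(per_field.loc[extra_n, "d_yield"].sum() * _KG_PER_T
              / per_field.loc[extra_n, "d_n"].sum())
        if extra_n.any()
        else float("nan")
    )
    totals = pd.Series(
        {
            "d_production_t": districts["d_production_t"].sum(),
            "d_n_use_t": districts["d_n_use_t"].sum(),
            "d_irrigation_events": districts["d_irrigation_events"].sum(),
            "d_profit_usd": districts["d_profit_usd"].sum(),
            "fraction_changed": float(per_field["changed"].mean()),
            "mean_d_yield_adopters_t_ha": (
                float(adopters["d_yield"].mean()) if len(adopters) else 0.0
            ),
            "mean_d_profit_adopters_usd_ha": (
                float(adopters["d_profit"].mean()) if len(adopters) else 0.0
            ),
            "nue_kg_grain_per_kg_n": nue,
        }
    )
    return ScenarioResult(districts=districts, totals=totals, spec=spec)


def derive_blanket_rate(
    model: YieldModel,
    matrix,
    variable: str = "n_rate",
    grid_step: float = 10.0,
) -> float:
    """Population-level non-limiting input rate from the partial dependence curve.

    The partial dependence of predicted yield on ``variable`` (mean ICE over
    all fields) is evaluated on the observed-range grid; the smallest rate
    attaining its maximum is returned. This is one defensible reading of
    "derived from the partial dependence plot" — a plateau criterion would
    give a lower rate.
    """
    from .decomposition import _batch_sweep

    grid, preds = _batch_sweep(model, matrix, variable, grid_step)
    pd_curve = preds.mean(axis=0)
    best = pd_curve.max()
    tol = 1e-9 * max(1.0, abs(best))
    return float(grid[pd_curve >= best - tol].min())
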