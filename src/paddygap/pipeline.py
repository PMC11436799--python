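"""End-to-end orchestration: generate/load → fit → decompose → explain →
cluster → hotspot → scenarios, with deterministic outputs and a run manifest.

A single seed fans out to per-stage seeds by fixed offsets so any stage can
be rerun in isolation and reproduce its output bitwise. The manifest records
the seed, a hash of the resolved configuration, package versions and every
stage's output files; it contains no timestamps, so identical configurations
produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import attainable_yield, decompose_sequential
from .hotspot import classify_hotspots, gi_star
from .model import Hyperparams, fit_yield_model, permutation_importance
from .scenarios import Prices, ScenarioSpec, apply_scenario, evaluate_scenario
from .shapley import assign_clusters, rank_importance, shap_values
from .survey import encode_features, read_district_areas, read_survey
from .synthetic import GeneratorConfig, generate_district_areas, generate_survey

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
_SEED_GENERATE = 0
_SEED_FIT = 1
_SEED_IMPORTANCE = 2


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str = "paddygap_out"
    seed: int = 0
    survey_csv: str | None = None          # when None, a landscape is generated
    district_areas_csv: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    n_trees: int = 200
    min_node_size: int = 50
    decile: float = 0.10
    grid_steps: dict = field(default_factory=dict)
    band_km: float = 10.0
    alpha: float = 0.05
    background_size: int = 128
    scenario_ids: tuple[int, ...] = (1, 2, 3, 4)
    paddy_usd_per_t: float | None = None
    irrigation_usd: float = 20.0
    n_usd_per_kg: float = 0.14

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["scenario_ids"] = tuple(raw.get("scenario_ids", (1, 2, 3, 4)))
        return PipelineConfig(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {
        "package": "paddygap",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": outputs,
    }

    def record(stage: str, name: str, path: Path) -> None:
        outputs[name] = str(path)
        manifest["stages"].setdefault(stage, []).append(str(path))

    # ---- fail-fast preconditions -------------------------------------------
    if config.scenario_ids and config.survey_csv and not config.district_areas_csv:
        raise PipelineError(
            "stage 'scenario': district areas CSV required when scenarios are "
            "enabled on a supplied survey"
        )

    # ---- stage: survey ------------------------------------------------------
    try:
        if config.survey_csv:
            table = read_survey(config.survey_csv)
            areas = (
                read_district_areas(config.district_areas_csv)
                if config.district_areas_csv
                else None
            )
        else:
            gen_cfg = GeneratorConfig(
                **{**config.generator, "seed": config.seed + _SEED_GENERATE}
            )
            table, truth = generate_survey(gen_cfg)
            areas_df = generate_district_areas(gen_cfg)
            areas = areas_df.set_index("district")["rice_area_ha"]
            survey_path = out / "survey.csv"
            table.frame.to_csv(survey_path, index=False)
            record("generate", "survey", survey_path)
            truth_path = out / "ground_truth.csv"
            truth.write(truth_path)
            record("generate", "ground_truth", truth_path)
            areas_path = out / "district_areas.csv"
            areas_df.to_csv(areas_path, index=False)
            record("generate", "district_areas", areas_path)
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"stage 'survey': {exc}") from exc

    # ---- stage: yield gaps --------------------------------------------------
    try:
        gaps = attainable_yield(table, decile=config.decile)
        gaps_path = out / "yield_gaps.csv"
        gaps.gaps.rename_axis("row").to_csv(gaps_path)
        record("gaps", "yield_gaps", gaps_path)
    except Exception as exc:
        raise PipelineError(f"stage 'gaps': {exc}") from exc

    # ---- stage: model -------------------------------------------------------
    try:
        matrix = encode_features(table)
        model = fit_yield_model(
            matrix,
            table.yields,
            Hyperparams(n_trees=config.n_trees, min_node_size=config.min_node_size),
            seed=config.seed + _SEED_FIT,
        )
        model_path = out / "model.joblib"
        model.save(model_path)
        record("fit", "model", model_path)
        ranking = permutation_importance(
            model, matrix, table.yields, seed=config.seed + _SEED_IMPORTANCE
        )
        imp_path = out / "importance.csv"
        ranking.frame.to_csv(imp_path, index=False)
        record("fit", "importance", imp_path)
    except Exception as exc:
        raise PipelineError(f"stage 'fit': {exc}") from exc

    # ---- stage: decomposition ----------------------------------------------
    try:
        management = [f for f in model.schema.management if f in model.features]
        decomp = decompose_sequential(
            model,
            matrix,
            ranking.restrict(management),
            grid_steps=config.grid_steps,
            y_att=gaps.y_att,
        )
        dec_path = out / "decomposition.csv"
        decomp.frame.assign(field_id=table.frame["field_id"].to_numpy()).to_csv(
            dec_path, index=False
        )
        record("decompose", "decomposition", dec_path)
        summary_path = out / "decomposition_summary.csv"
        decomp.summary().to_csv(summary_path)
        record("decompose", "decomposition_summary", summary_path)
    except Exception as exc:
        raise PipelineError(f"stage 'decompose': {exc}") from exc

    # ---- stage: attribution -------------------------------------------------
    try:
        shap = shap_values(model, matrix, background_size=config.background_size)
        shap_path = out / "shap_values.csv"
        shap.values.assign(field_id=table.frame["field_id"].to_numpy()).to_csv(
            shap_path, index=False
        )
        record("explain", "shap_values", shap_path)
        display = (
            matrix.scaled()
            .stack()
            .rename("scaled_value")
            .to_frame()
            .join(shap.values.stack().rename("phi"))
            .rename_axis(["row", "feature"])
            .reset_index()
        )
        display_path = out / "shap_display.csv"
        display.to_csv(display_path, index=False)
        record("explain", "shap_display", display_path)

        clusters = assign_clusters(shap, districts=table.frame["district"])
        cl_path = out / "clusters.csv"
        pd.DataFrame(
            {
                "field_id": table.frame["field_id"].to_numpy(),
                "cluster": clusters.labels.to_numpy(),
            }
        ).to_csv(cl_path, index=False)
        record("explain", "clusters", cl_path)
    except Exception as exc:
        raise PipelineError(f"stage 'explain': {exc}") from exc

    # ---- stage: hotspot -----------------------------------------------------
    try:
        hs_frames = []
        for variable in ("n_rate", "irrigation_count"):
            res = gi_star(
                table.frame["lat"].to_numpy(),
                table.frame["lon"].to_numpy(),
                shap.values[variable].to_numpy(),
                band_km=config.band_km,
            )
            classify_hotspots(res, alpha=config.alpha)
            hs_frames.append(
                pd.DataFrame(
                    {
                        "field_id": table.frame["field_id"].to_numpy(),
                        "lat": table.frame["lat"].to_numpy(),
                        "lon": table.frame["lon"].to_numpy(),
                        "variable": variable,
                        "z": res.frame["z"].to_numpy(),
                        "category": res.frame["category"].to_numpy(),
                    }
                )
            )
        hs_path = out / "hotspots.csv"
        pd.concat(hs_frames, ignore_index=True).to_csv(hs_path, index=False)
        record("hotspot", "hotspots", hs_path)
    except Exception as exc:
        raise PipelineError(f"stage 'hotspot': {exc}") from exc

    # ---- stage: scenarios ---------------------------------------------------
    try:
        if config.scenario_ids:
            if areas is None:
                raise ValueError("district areas unavailable")
            prices = Prices(
                irrigation_usd=config.irrigation_usd,
                n_usd_per_kg=config.n_usd_per_kg,
                paddy_usd_per_t=config.paddy_usd_per_t,
            )
            totals_rows = {}
            for sid in config.scenario_ids:
                spec = ScenarioSpec.preset(sid, prices=prices)
                modified, mask = apply_scenario(table, spec, clusters=clusters)
                result = evaluate_scenario(model, table, modified, areas, spec, mask)
                s_path = out / f"scenario_{sid}_districts.csv"
                result.districts.to_csv(s_path)
                record("scenario", f"scenario_{sid}", s_path)
                totals_rows[sid] = result.totals
            totals_path = out / "scenario_totals.csv"
            pd.DataFrame(totals_rows).rename_axis("quantity").to_csv(totals_path)
            record("scenario", "scenario_totals", totals_path)
    except Exception as exc:
        raise PipelineError(f"stage 'scenario': {exc}") from exc

    manifest["summary"] = {
        "n_records": int(len(table)),
        "attainable_yield_t_ha": gaps.y_att,
        "oob_r2": model.oob_r2,
        "top_management_constraints": ranking.restrict(
            [f for f in model.schema.management if f in model.features]
        ).features[:2],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    outputs["manifest"] = str(manifest_path)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return manifest
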