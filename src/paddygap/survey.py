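"""Survey data model: validation, IO, and feature encoding.

The unit of analysis is a field-year record from a landscape-scale crop
assessment survey: where the field is (WGS84 lat/lon, state, district),
what the farmer did (fertilizer rates, irrigations, sowing date, variety
class), the seasonal weather the crop saw (cumulative solar radiation and
mean daily maximum temperature, sowing to harvest), and the rice yield
obtained (t ha⁻¹).

Predictors are partitioned into a *management* group (what an intervention
can change) and a *biophysical* group (what it cannot); the partition is
asserted at load time and shared by every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the survey CSV.
SURVEY_COLUMNS = [
    "field_id",
    "lat",
    "lon",
    "state",
    "district",
    "year",
    "yield_obs",
    "n_rate",
    "p_rate",
    "k_rate",
    "zn_rate",
    "irrigation_count",
    "sowing_doy",
    "variety_class",
    "weather_srad",
    "weather_tmax",
]

MANAGEMENT_FEATURES = (
    "n_rate",
    "p_rate",
    "k_rate",
    "zn_rate",
    "irrigation_count",
    "sowing_doy",
    "variety_class",
)
BIOPHYSICAL_FEATURES = ("weather_srad", "weather_tmax")

#: Ordinal maturity-class levels, shortest to longest duration.
VARIETY_LEVELS = ("short", "medium", "long")

RATE_COLUMNS = ("n_rate", "p_rate", "k_rate", "zn_rate")

YIELD_MAX = 15.0  # t ha⁻¹; crop-cut rice yields above this are data errors


class ValidationError(ValueError):
    """Raised when a survey table violates a schema-level invariant."""


@dataclass(frozen=True)
class FeatureSchema:
    """Partition of the predictor set into management and biophysical groups."""

    management: tuple[str, ...] = MANAGEMENT_FEATURES
    biophysical: tuple[str, ...] = BIOPHYSICAL_FEATURES
    categorical_levels: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"variety_class": VARIETY_LEVELS}
    )

    def __post_init__(self) -> None:
        overlap = set(self.management) & set(self.biophysical)
        if overlap:
            raise ValidationError(
                f"features in both management and biophysical groups: {sorted(overlap)}"
            )

    @property
    def features(self) -> tuple[str, ...]:
        return self.management + self.biophysical

    def group_of(self, name: str) -> str:
        if name in self.management:
            return "management"
        if name in self.biophysical:
            return "biophysical"
        raise KeyError(f"{name!r} is not a predictor in this schema")


@dataclass
class SurveyTable:
    """Validated field-year records plus the shared feature schema."""

    frame: pd.DataFrame
    schema: FeatureSchema = field(default_factory=FeatureSchema)
    state: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"missing mandatory columns: {missing}")
        if self.state is None and len(self.frame):
            states = self.frame["state"].unique()
            self.state = states[0] if len(states) == 1 else None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def yields(self) -> np.ndarray:
        return self.frame["yield_obs"].to_numpy(float)

    def counts(self) -> pd.Series:
        """Record counts per (state, district)."""
        return self.frame.groupby(["state", "district"], observed=True).size()


def _row_problems(df: pd.DataFrame, schema: FeatureSchema) -> pd.Series:
    """Per-row validation diagnostics; empty string means the row is clean."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        reasons[mask] = reasons[mask].where(reasons[mask] == "", reasons[mask] + "; ")
        reasons[mask] += reason

    numeric = [
        "lat", "lon", "year", "yield_obs", *RATE_COLUMNS,
        "irrigation_count", "sowing_doy", "weather_srad", "weather_tmax",
    ]
    coerced = {c: pd.to_numeric(df[c], errors="coerce") for c in numeric}
    for c in ("lat", "lon"):
        flag(~np.isfinite(coerced[c]), f"unparseable coordinate {c}")
    flag(df[SURVEY_COLUMNS].isna().any(axis=1), "missing value")
    y = coerced["yield_obs"]
    flag(~((y > 0) & (y < YIELD_MAX)), f"yield_obs outside (0, {YIELD_MAX})")
    for c in RATE_COLUMNS:
        flag(coerced[c] < 0, f"negative {c}")
    irr = coerced["irrigation_count"]
    flag((irr < 0) | (irr != np.floor(irr)), "irrigation_count not a non-negative integer")
    doy = coerced["sowing_doy"]
    flag((doy < 1) | (doy > 366), "sowing_doy outside 1..366")
    for col, levels in schema.categorical_levels.items():
        flag(~df[col].astype(str).isin(levels), f"unknown {col} level")
    return reasons


def validate_frame(
    df: pd.DataFrame, schema: FeatureSchema | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid, rejected-with-reason) parts.

    Rows violating record-level invariants are rejected, not imputed;
    duplicated (field_id, year) keys are a table-level error and raise.
    """
    schema = schema or FeatureSchema()
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory columns: {missing}")

    reasons = _row_problems(df, schema)
    bad = reasons != ""
    rejected = df.loc[bad].assign(reason=reasons[bad])
    valid = df.loc[~bad].copy()
    for c in rejected.index:
        logger.warning("rejected row %s: %s", c, rejected.loc[c, "reason"])

    dup = valid.duplicated(subset=["field_id", "year"], keep=False)
    if dup.any():
        keys = (
            valid.loc[dup, ["field_id", "year"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValidationError(f"duplicated field_id+year keys: {sorted(keys)}")

    # normalize dtypes once so downstream stages never re-coerce
    for c in ("lat", "lon", "yield_obs", *RATE_COLUMNS, "weather_srad", "weather_tmax"):
        valid[c] = pd.to_numeric(valid[c]).astype(float)
    for c in ("year", "irrigation_count", "sowing_doy"):
        valid[c] = pd.to_numeric(valid[c]).astype(int)
    valid["variety_class"] = valid["variety_class"].astype(str)
    return valid, rejected


def read_survey(
    path: str | Path,
    schema: FeatureSchema | None = None,
    state: str | None = None,
) -> SurveyTable:
    """Read and validate a survey CSV; invalid rows are dropped with a log entry."""
    schema = schema or FeatureSchema()
    df = pd.read_csv(path)
    valid, rejected = validate_frame(df, schema)
    table = SurveyTable(valid.reset_index(drop=True), schema=schema, state=state)
    logger.info(
        "read %d records from %s (%d rejected); per-district counts:\n%s",
        len(table), path, len(rejected), table.counts().to_string(),
    )
    return table


def write_survey(table: SurveyTable, path: str | Path) -> None:
    table.frame.to_csv(path, columns=SURVEY_COLUMNS, index=False)


def read_district_areas(path: str | Path) -> pd.Series:
    """District rice areas (ha) keyed by district name."""
    df = pd.read_csv(path)
    for col in ("district", "rice_area_ha"):
        if col not in df.columns:
            raise ValidationError(f"district-areas CSV missing column {col!r}")
    areas = df.set_index("district")["rice_area_ha"].astype(float)
    if (areas < 0).any():
        raise ValidationError("negative rice_area_ha")
    return areas


@dataclass
class FeatureMatrix:
    """Numeric predictor matrix with its categorical encoding and display scaling.

    Raw (unscaled) values are what the model consumes; the min-max scaling is
    retained only for attribution display, mirroring how survey variables are
    normalized for summary plots. A constant column scales to 0 by convention.
    """

    frame: pd.DataFrame
    encoding: dict[str, dict[str, int]]
    feature_range: pd.DataFrame  # rows: min, max; columns: features
    schema: FeatureSchema

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def to_numpy(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    def scaled(self) -> pd.DataFrame:
        lo = self.feature_range.loc["min"]
        hi = self.feature_range.loc["max"]
        span = (hi - lo).replace(0.0, np.nan)
        out = (self.frame - lo) / span
        return out.fillna(0.0)

    def decode(self, frame: pd.DataFrame | None = None) -> pd.DataFrame:
        """Map ordinal codes back to categorical labels (round-trip inverse)."""
        frame = self.frame if frame is None else frame
        out = frame.copy()
        for col, mapping in self.encoding.items():
            inverse = {code: level for level, code in mapping.items()}
            out[col] = out[col].map(inverse)
        return out

    def with_values(self, **columns: np.ndarray) -> "FeatureMatrix":
        """Copy with some columns replaced (used for counterfactual sweeps)."""
        frame = self.frame.copy()
        for name, values in columns.items():
            if name not in frame.columns:
                raise KeyError(f"{name!r} not in feature matrix")
            frame[name] = values
        return FeatureMatrix(frame, self.encoding, self.feature_range, self.schema)


def encode_features(
    table: SurveyTable, encoding: dict[str, dict[str, int]] | None = None
) -> FeatureMatrix:
    """Encode the predictor columns of a survey table as a numeric matrix.

    Categorical predictors are ordinally coded (level order as declared in the
    schema). Passing a previously fitted ``encoding`` enforces the same codes;
    an unseen level then raises instead of being silently coerced.
    """
    schema = table.schema
    frame = table.frame[list(schema.features)].copy()
    if encoding is None:
        encoding = {
            col: {level: code for code, level in enumerate(levels)}
            for col, levels in schema.categorical_levels.items()
        }
    for col, mapping in encoding.items():
        observed = frame[col].astype(str)
        unseen = sorted(set(observed) - set(mapping))
        if unseen:
            raise ValidationError(f"unseen {col} levels at encode time: {unseen}")
        frame[col] = observed.map(mapping).astype(float)
    frame = frame.astype(float)
    feature_range = pd.DataFrame(
        {c: [frame[c].min(), frame[c].max()] for c in frame.columns},
        index=["min", "max"],
    )
    return FeatureMatrix(frame, encoding, feature_range, schema)
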