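"""Synthetic survey landscapes with known yield response and planted constraints.

The generator emulates the *structure* of a landscape-scale crop assessment
survey — schema, marginal ranges, spatially clustered management, and a yield
surface with diminishing returns to inputs — not the joint distribution of any
real survey. Its value is the recorded ground truth: the exact expected yield
of every field and whether nitrogen or irrigation truly limits it, so that the
model, decomposition, attribution, clustering and hotspot stages can all be
checked against a known answer.

Yield response
--------------
Expected yield is additive with Mitscherlich-type (saturating-exponential)
responses to N fertilizer and irrigation, both capped at an agronomic plateau,
linear terms for seasonal weather, sowing date and the minor nutrients, a
small ordinal variety effect, and i.i.d. Gaussian noise:

    E[y] = b0 + aN·(1 − exp(−min(N, Np)/kN)) + aI·(1 − exp(−min(I, Ip)/kI))
           + weather + date + minor nutrients + variety

Each field belongs to a latent limitation class (adequate/deficient in N,
adequate/deficient in irrigation) drawn with configurable shares; deficient
fields draw input levels well below the response plateau. Circular "hotspots"
override the class spatially, planting contiguous constraint zones that the
Gi* stage should rediscover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hotspot import haversine_km
from .survey import (
    SURVEY_COLUMNS,
    FeatureSchema,
    SurveyTable,
)

#: Latent limitation classes and their default shares (irrigation sign first).
DEFAULT_CLASS_PROBS = {"I+N+": 0.35, "I-N+": 0.35, "I-N-": 0.20, "I+N-": 0.10}

VARIETY_LEVELS = ("short", "medium", "long")


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class ResponseParams:
    """Coefficients of the true yield-response surface (t ha⁻¹ scale)."""

    base_yield: float = 1.2
    n_max_gain: float = 2.0        # asymptotic N response, t ha⁻¹
    n_scale: float = 60.0          # N response e-folding scale, kg ha⁻¹
    n_plateau: float = 180.0       # N level beyond which response is exactly flat
    irr_max_gain: float = 1.8      # asymptotic irrigation response, t ha⁻¹
    irr_scale: float = 2.2         # irrigation e-folding scale, events
    irr_plateau: float = 5.0       # irrigation count beyond which flat
    p_slope: float = 0.002         # t ha⁻¹ per kg P ha⁻¹
    zn_slope: float = 0.012        # t ha⁻¹ per kg Zn ha⁻¹
    k_slope: float = 0.0           # K deliberately null: a no-signal feature
    doy_slope: float = -0.004      # t ha⁻¹ per day of delayed sowing
    doy_ref: float = 152.0
    srad_slope: float = 5e-4       # t ha⁻¹ per MJ m⁻²
    srad_ref: float = 2000.0
    tmax_slope: float = 0.04       # t ha⁻¹ per °C
    tmax_ref: float = 32.0
    variety_effect: tuple[float, ...] = (0.0, 0.15, 0.30)


@dataclass(frozen=True)
class ManagementDistributions:
    """Sampling ranges of management and weather variables by limitation class."""

    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    n_deficient: tuple[float, float] = (20.0, 80.0)
    n_adequate: tuple[float, float] = (130.0, 200.0)
    irr_deficient: tuple[int, int] = (1, 2)
    irr_adequate: tuple[int, int] = (5, 7)
    p_range: tuple[float, float] = (0.0, 60.0)
    k_range: tuple[float, float] = (0.0, 60.0)
    zn_range: tuple[float, float] = (0.0, 10.0)
    doy_range: tuple[int, int] = (152, 200)
    srad_range: tuple[float, float] = (1600.0, 2400.0)
    tmax_range: tuple[float, float] = (29.0, 35.0)


@dataclass(frozen=True)
class HotspotCenter:
    """A planted circular constraint zone.

    ``variable`` is ``"n"`` or ``"irrigation"``; ``sign`` −1 forces the
    deficient input distribution inside the circle (a constraint cold spot),
    +1 forces the adequate one.
    """

    lat: float
    lon: float
    radius_km: float
    variable: str = "n"
    sign: int = -1


@dataclass(frozen=True)
class GeneratorConfig:
    n_fields: int = 5000
    n_districts: int = 12
    #: (lat_min, lat_max, lon_min, lon_max), WGS84 decimal degrees
    spatial_extent: tuple[float, float, float, float] = (25.0, 27.0, 84.0, 86.0)
    response_params: ResponseParams = field(default_factory=ResponseParams)
    noise_sd: float = 0.4
    management: ManagementDistributions = field(default_factory=ManagementDistributions)
    hotspot_centers: tuple[HotspotCenter, ...] = (
        HotspotCenter(26.55, 85.55, 15.0, "n", -1),
        HotspotCenter(25.40, 84.45, 18.0, "irrigation", -1),
    )
    state_name: str = "Synthetic Eastern"
    year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 10 * self.n_districts:
            raise GeneratorConfigError(
                f"n_fields={self.n_fields} must be ≥ 10 × n_districts={self.n_districts}"
            )
        if self.noise_sd < 0:
            raise GeneratorConfigError(f"noise_sd={self.noise_sd} must be ≥ 0")
        lat0, lat1, lon0, lon1 = self.spatial_extent
        if not (lat1 > lat0 and lon1 > lon0):
            raise GeneratorConfigError(f"spatial_extent={self.spatial_extent} is empty")
        m = self.management
        for name in ("n_deficient", "n_adequate", "p_range", "k_range", "zn_range"):
            lo, hi = getattr(m, name)
            if lo < 0 or hi < lo:
                raise GeneratorConfigError(f"management.{name}={(lo, hi)} invalid")
        for name in ("irr_deficient", "irr_adequate"):
            lo, hi = getattr(m, name)
            if lo < 0 or hi < lo:
                raise GeneratorConfigError(f"management.{name}={(lo, hi)} invalid")
        total = sum(m.class_probs.values())
        if abs(total - 1.0) > 1e-9 or min(m.class_probs.values()) < 0:
            raise GeneratorConfigError(
                f"management.class_probs must be a probability vector, got {dict(m.class_probs)}"
            )
        for h in self.hotspot_centers:
            if h.radius_km <= 0 or h.variable not in ("n", "irrigation") or h.sign not in (-1, 1):
                raise GeneratorConfigError(f"hotspot_centers entry invalid: {h}")


@dataclass
class GroundTruth:
    """Per-field truth recorded at generation time.

    A field is N-limited iff raising N to the response plateau raises true
    expected yield by more than ``noise_sd / 2`` (likewise for irrigation);
    ``attainable_true`` is the top-decile mean of true expected yields.
    """

    frame: pd.DataFrame  # field_id, true_yield, n_limited, irrigation_limited, latent_class
    attainable_true: float
    config: GeneratorConfig

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _saturating(x: np.ndarray, max_gain: float, scale: float, plateau: float) -> np.ndarray:
    return max_gain * (1.0 - np.exp(-np.minimum(x, plateau) / scale))


def true_response(record, config: GeneratorConfig) -> np.ndarray | float:
    """Expected (noise-free) yield for one record or a frame of records.

    Monotone non-decreasing in N and irrigation up to their plateaus and
    exactly flat beyond; analytically differentiable below plateau
    (d/dN = aN/kN · exp(−N/kN)).
    """
    scalar = not isinstance(record, pd.DataFrame)
    df = pd.DataFrame([record]) if scalar else record
    r = config.response_params
    variety_codes = df["variety_class"].map(
        {lvl: i for i, lvl in enumerate(VARIETY_LEVELS)}
    ).to_numpy()
    effects = np.asarray(r.variety_effect)[variety_codes.astype(int)]
    y = (
        r.base_yield
        + _saturating(df["n_rate"].to_numpy(float), r.n_max_gain, r.n_scale, r.n_plateau)
        + _saturating(
            df["irrigation_count"].to_numpy(float), r.irr_max_gain, r.irr_scale, r.irr_plateau
        )
        + r.p_slope * df["p_rate"].to_numpy(float)
        + r.k_slope * df["k_rate"].to_numpy(float)
        + r.zn_slope * df["zn_rate"].to_numpy(float)
        + r.doy_slope * (df["sowing_doy"].to_numpy(float) - r.doy_ref)
        + r.srad_slope * (df["weather_srad"].to_numpy(float) - r.srad_ref)
        + r.tmax_slope * (df["weather_tmax"].to_numpy(float) - r.tmax_ref)
        + effects
    )
    return float(y[0]) if scalar else y


def _district_grid(config: GeneratorConfig) -> pd.DataFrame:
    """Rectangular district cells tiling the extent, row-major names."""
    lat0, lat1, lon0, lon1 = config.spatial_extent
    ncols = int(np.ceil(np.sqrt(config.n_districts)))
    nrows = int(np.ceil(config.n_districts / ncols))
    cells = []
    for k in range(config.n_districts):
        i, j = divmod(k, ncols)
        cells.append(
            {
                "district": f"district_{k + 1:02d}",
                "lat_lo": lat0 + (lat1 - lat0) * i / nrows,
                "lat_hi": lat0 + (lat1 - lat0) * (i + 1) / nrows,
                "lon_lo": lon0 + (lon1 - lon0) * j / ncols,
                "lon_hi": lon0 + (lon1 - lon0) * (j + 1) / ncols,
            }
        )
    return pd.DataFrame(cells)


def generate_survey(config: GeneratorConfig) -> tuple[SurveyTable, GroundTruth]:
    """Draw a synthetic survey landscape plus its ground truth.

    Deterministic for a fixed config (identical seed ⇒ bitwise-identical
    tables). With ``noise_sd=0`` observed yields equal the true response.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fields
    m = config.management
    r = config.response_params

    cells = _district_grid(config)
    district_idx = rng.integers(0, config.n_districts, size=n)
    cell = cells.iloc[district_idx].reset_index(drop=True)
    lat = rng.uniform(cell["lat_lo"].to_numpy(), cell["lat_hi"].to_numpy())
    lon = rng.uniform(cell["lon_lo"].to_numpy(), cell["lon_hi"].to_numpy())

    classes = list(m.class_probs)
    latent = rng.choice(classes, size=n, p=[m.class_probs[c] for c in classes])
    irr_deficient = np.char.startswith(latent.astype(str), "I-")
    n_deficient = np.char.endswith(latent.astype(str), "N-")

    # spatial overrides: planted constraint circles
    for h in config.hotspot_centers:
        inside = haversine_km(lat, lon, h.lat, h.lon) <= h.radius_km
        if h.variable == "n":
            n_deficient = np.where(inside, h.sign < 0, n_deficient)
        else:
            irr_deficient = np.where(inside, h.sign < 0, irr_deficient)
    latent = np.where(irr_deficient, "I-", "I+").astype(object) + np.where(
        n_deficient, "N-", "N+"
    )

    n_rate = np.where(
        n_deficient,
        rng.uniform(*m.n_deficient, size=n),
        rng.uniform(*m.n_adequate, size=n),
    )
    irrigation = np.where(
        irr_deficient,
        rng.integers(m.irr_deficient[0], m.irr_deficient[1] + 1, size=n),
        rng.integers(m.irr_adequate[0], m.irr_adequate[1] + 1, size=n),
    )

    frame = pd.DataFrame(
        {
            "field_id": [f"F{i + 1:06d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "state": config.state_name,
            "district": cell["district"].to_numpy(),
            "year": config.year,
            "yield_obs": np.nan,
            "n_rate": n_rate,
            "p_rate": rng.uniform(*m.p_range, size=n),
            "k_rate": rng.uniform(*m.k_range, size=n),
            "zn_rate": rng.uniform(*m.zn_range, size=n),
            "irrigation_count": irrigation.astype(int),
            "sowing_doy": rng.integers(m.doy_range[0], m.doy_range[1] + 1, size=n),
            "variety_class": rng.choice(VARIETY_LEVELS, size=n),
            "weather_srad": rng.uniform(*m.srad_range, size=n),
            "weather_tmax": rng.uniform(*m.tmax_range, size=n),
        },
        columns=SURVEY_COLUMNS,
    )

    true_yield = np.asarray(true_response(frame, config), float)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    # floor far in the left tail so observed yields stay strictly positive
    frame["yield_obs"] = np.maximum(true_yield + noise, 0.1)

    # limitation labels from the generating response itself
    at_n_plateau = frame.assign(n_rate=r.n_plateau)
    at_irr_plateau = frame.assign(irrigation_count=r.irr_plateau)
    gain_n = np.asarray(true_response(at_n_plateau, config)) - true_yield
    gain_irr = np.asarray(true_response(at_irr_plateau, config)) - true_yield
    threshold = config.noise_sd / 2.0
    truth_frame = pd.DataFrame(
        {
            "field_id": frame["field_id"],
            "true_yield": true_yield,
            "n_limited": gain_n > threshold,
            "irrigation_limited": gain_irr > threshold,
            "latent_class": latent,
        }
    )
    cutoff = np.quantile(true_yield, 0.9)
    attainable_true = float(true_yield[true_yield >= cutoff].mean())

    table = SurveyTable(frame, schema=FeatureSchema(), state=config.state_name)
    return table, GroundTruth(truth_frame, attainable_true, config)


def generate_district_areas(config: GeneratorConfig) -> pd.DataFrame:
    """Fabricate district rice areas (ha), seeded independently of the survey."""
    rng = np.random.default_rng(config.seed + 7919)
    districts = _district_grid(config)["district"]
    return pd.DataFrame(
        {
            "district": districts,
            "rice_area_ha": rng.uniform(50_000, 200_000, size=len(districts)).round(0),
        }
    )
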