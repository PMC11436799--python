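"""Attainable yields, yield gaps, and sequential ICE-based gap attribution.

The attainable yield of a region is the mean observed yield of its top decile
of fields — a pragmatic benchmark already realised by some farmers rather
than a theoretical potential. The attainable yield gap of every other field
is the distance to that benchmark.

How much of the gap the two leading management constraints explain is
quantified with individual conditional expectation (ICE) curves: for each
field, the fitted model's prediction is swept over a grid of levels of the
most important management variable with everything else held at the field's
reported values. The gain from moving the variable to its predicted-optimal
level is Yg1; with that substitution frozen in, the sweep is repeated for the
second variable to give Yg2. Both gains are non-negative by construction
because each grid includes the field's current level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ImportanceRanking, YieldModel
from .survey import FeatureMatrix, SurveyTable

#: Default sweep resolution per management variable, in the variable's units
#: (kg ha⁻¹ for nutrients, events for irrigation, days for sowing date) —
#: comparable to the measurement granularity of each practice.
DEFAULT_GRID_STEPS = {
    "n_rate": 10.0,
    "irrigation_count": 1.0,
    "p_rate": 5.0,
    "k_rate": 10.0,
    "zn_rate": 2.0,
    "sowing_doy": 5.0,
}

_REL_TOL = 1e-9  # tie tolerance when comparing curve maxima


@dataclass
class GapSummary:
    """Attainable yield and the per-field gaps to it."""

    y_att: float                   # mean yield of the top decile, t ha⁻¹
    gaps: pd.Series                # Yg_a per non-top-decile field, t ha⁻¹
    cutoff: float                  # decile cutoff yield, t ha⁻¹
    decile: float
    state: str | None = None


def attainable_yield(
    table: SurveyTable, decile: float = 0.10
) -> GapSummary:
    """Top-decile-mean attainable yield and per-field attainable gaps.

    Fields with yield ≥ the empirical (1 − decile) quantile (linear
    interpolation; ties at the cutoff included) form the benchmark group;
    gaps are reported for the remaining fields only and are strictly positive
    because the cutoff never exceeds the benchmark mean.
    """
    if len(table) == 0:
        raise ValueError("empty survey table")
    if len(table) < 10:
        raise ValueError(f"need ≥ 10 records to estimate a top decile, got {len(table)}")
    y = table.yields
    cutoff = float(np.quantile(y, 1.0 - decile))
    top = y >= cutoff
    y_att = float(y[top].mean())
    gaps = pd.Series(
        y_att - y[~top],
        index=table.frame.index[~top],
        name="yield_gap",
    )
    return GapSummary(y_att=y_att, gaps=gaps, cutoff=cutoff, decile=decile, state=table.state)


@dataclass
class IceCurve:
    """One field's predicted yield as a single input is swept over a grid."""

    variable: str
    grid: np.ndarray               # swept input levels (reported value included)
    predictions: np.ndarray        # predicted yield at each grid level, t ha⁻¹
    reported_value: float
    reported_prediction: float

    @property
    def maximum(self) -> float:
        return float(self.predictions.max())

    @property
    def argmax(self) -> float:
        """Optimal input level: the reported value if it ties the maximum,
        else the smallest level attaining it (resource-minimizing)."""
        best = self.maximum
        tol = _REL_TOL * max(1.0, abs(best))
        if self.reported_prediction >= best - tol:
            return float(self.reported_value)
        hit = self.grid[self.predictions >= best - tol]
        return float(hit.min())


def _sweep_grid(model: YieldModel, variable: str, grid_step: float | None) -> np.ndarray:
    """Grid over the observed training range of ``variable``; no extrapolation."""
    lo = float(model.feature_range.loc["min", variable])
    hi = float(model.feature_range.loc["max", variable])
    if variable in model.schema.categorical_levels:
        return np.arange(lo, hi + 0.5)  # ordinal codes of the observed levels
    step = grid_step if grid_step is not None else DEFAULT_GRID_STEPS.get(variable)
    if step is None or step <= 0:
        raise ValueError(f"positive grid_step required for numeric variable {variable!r}")
    grid = np.arange(lo, hi + step * 1e-9, step)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    return grid


def ice_sweep(
    model: YieldModel,
    record: pd.Series,
    variable: str,
    grid_step: float | None = None,
) -> IceCurve:
    """ICE curve for one field: sweep ``variable``, hold all else as reported."""
    if variable not in model.features:
        raise ValueError(f"variable {variable!r} not in model schema")
    grid = _sweep_grid(model, variable, grid_step)
    reported = float(record[variable])
    if reported not in grid:
        grid = np.sort(np.append(grid, reported))
    frame = pd.DataFrame([record[list(model.features)]] * len(grid))
    frame[variable] = grid
    preds = model.predict(frame.astype(float))
    reported_pred = float(preds[grid == reported][0])
    return IceCurve(variable, grid, preds, reported, reported_pred)


def _batch_sweep(
    model: YieldModel, matrix: FeatureMatrix, variable: str, grid_step: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ICE over all records: (grid, predictions[n, g])."""
    grid = _sweep_grid(model, variable, grid_step)
    frame = matrix.frame[list(model.features)]
    n, g = len(frame), len(grid)
    tiled = frame.loc[frame.index.repeat(g)].reset_index(drop=True)
    tiled[variable] = np.tile(grid, n)
    preds = model.predict(tiled).reshape(n, g)
    return grid, preds


@dataclass
class DecompositionResult:
    """Per-field sequential gap closure for the top-2 management constraints."""

    frame: pd.DataFrame            # yg1, yg2, combined, y0, y_step1, y_step2, opt levels
    variables: tuple[str, str]
    y_att: float | None = None     # state attainable yield, for relative expression

    def relative(self) -> pd.DataFrame:
        """Yg1, Yg2 and their sum as fractions of the state attainable yield."""
        if self.y_att is None:
            raise ValueError("no attainable yield attached")
        return self.frame[["yg1", "yg2", "combined"]] / self.y_att

    def summary(self) -> pd.DataFrame:
        """Quartile summary of Yg1, Yg2 and the combined closure."""
        return self.frame[["yg1", "yg2", "combined"]].describe(
            percentiles=[0.25, 0.5, 0.75]
        )


def decompose_sequential(
    model: YieldModel,
    matrix: FeatureMatrix,
    ranking: ImportanceRanking,
    grid_steps: dict[str, float] | None = None,
    y_att: float | None = None,
) -> DecompositionResult:
    """Sequential two-variable ICE decomposition of the yield gap.

    ``ranking`` must already be restricted to management variables; its top
    two entries are swept in order. For each field, the first variable is set
    to its ICE-optimal level before the second sweep, so Yg2 is the *extra*
    closure beyond Yg1 and the combined closure is exactly Yg1 + Yg2.
    """
    if len(ranking.frame) < 2:
        raise ValueError("need at least 2 ranked management variables to decompose")
    steps = {**DEFAULT_GRID_STEPS, **(grid_steps or {})}
    var1, var2 = ranking.features[:2]

    y0 = model.predict(matrix)

    grid1, preds1 = _batch_sweep(model, matrix, var1, steps.get(var1))
    y_step1 = np.maximum(preds1.max(axis=1), y0)
    opt1 = _tied_argmax(grid1, preds1, matrix.frame[var1].to_numpy(float), y0)

    substituted = matrix.with_values(**{var1: opt1})
    y_sub = model.predict(substituted)  # equals y_step1 by construction
    grid2, preds2 = _batch_sweep(model, substituted, var2, steps.get(var2))
    y_step2 = np.maximum(preds2.max(axis=1), y_sub)
    opt2 = _tied_argmax(grid2, preds2, substituted.frame[var2].to_numpy(float), y_sub)

    yg1 = y_step1 - y0
    yg2 = y_step2 - y_step1
    frame = pd.DataFrame(
        {
            "y0": y0,
            "y_step1": y_step1,
            "y_step2": y_step2,
            "yg1": yg1,
            "yg2": yg2,
            "combined": yg1 + yg2,
            f"{var1}_opt": opt1,
            f"{var2}_opt": opt2,
        },
        index=matrix.frame.index,
    )
    return DecompositionResult(frame, (var1, var2), y_att=y_att)


def _tied_argmax(
    grid: np.ndarray, preds: np.ndarray, reported: np.ndarray, reported_pred: np.ndarray
) -> np.ndarray:
    """Vectorized optimal-level rule: reported value if it ties the max,
    else the smallest grid level attaining the max."""
    best = preds.max(axis=1)
    tol = _REL_TOL * np.maximum(1.0, np.abs(best))
    at_max = preds >= (best - tol)[:, None]
    # first (smallest) grid index attaining the max
    first_idx = at_max.argmax(axis=1)
    opt = grid[first_idx]
    keep_reported = reported_pred >= best - tol
    return np.where(keep_reported, reported, opt)
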