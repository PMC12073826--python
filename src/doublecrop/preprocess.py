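"""Denoising of raw field-scale NDVI series into a fixed 36-point annual grid.

Four steps, applied in order:

1. **Jump correction** — NDVI cannot rise faster than canopy can grow
   (default cap 0.018/day, which forces planting-to-peak to take at least a
   month); a too-fast rise means the *earlier* point was depressed by
   clouds, so that point is replaced by linear interpolation.
2. **Negative clipping** — negative NDVI means no vegetation; its magnitude
   is noise and would inflate the ratio method's normalization denominator,
   so negatives are set to zero.
3. **Regularization** — maximum-value compositing onto 36 fixed 10-day
   windows (day-of-year 1, 11, …, 351; the last window absorbs the year
   end). The max is used because atmospheric contamination only lowers NDVI.
4. **Savitzky–Golay smoothing** — local cubic least-squares fit over a
   7-point moving window; reproduces polynomials up to degree 3 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .timeseries_io import FieldMeta, FieldSeries

logger = logging.getLogger(__name__)

N_WINDOWS = 36
WINDOW_STARTS = np.arange(1, 352, 10)  # DOY 1, 11, ..., 351

MAX_DAILY_INCREASE = 0.018
WINDOW_DAYS = 10
SG_WINDOW = 7
SG_POLYORDER = 3
_JUMP_PASS_LIMIT = 20


class UnusableSeriesError(ValueError):
    """The series has no usable observations for the target year."""


@dataclass(frozen=True)
class SmoothSeries:
    """Equal-length (36-point) regularized, smoothed annual NDVI series.

    Values live in NDVI units; Savitzky–Golay smoothing may overshoot the
    composited values slightly, so the contract is [−0.05, 1.05] rather
    than [0, 1]. Values are deliberately not re-clipped after smoothing.
    """

    meta: FieldMeta
    year: int
    window_starts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ws = np.asarray(self.window_starts, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "window_starts", ws)
        object.__setattr__(self, "values", vals)
        if len(ws) != len(vals):
            raise ValueError("window_starts and values length mismatch")
        if len(vals) != N_WINDOWS:
            raise ValueError(f"expected {N_WINDOWS} windows, got {len(vals)}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite values")

    def with_values(self, values: np.ndarray) -> "SmoothSeries":
        return replace(self, values=np.asarray(values, dtype=float))


def correct_jumps(
    series: FieldSeries, max_daily_increase: float = MAX_DAILY_INCREASE
) -> FieldSeries:
    """Repair cloud-depressed points that produce impossibly fast NDVI rises.

    For every adjacent pair where the per-day increase exceeds the cap, the
    earlier value is replaced by linear interpolation between its neighbours
    (the first point, having no left neighbour, takes the value of its right
    neighbour). One repair can expose another violation, so passes repeat
    until clean or a pass limit is hit. Decreases are never modified.
    """
    if len(series.observations) < 3:
        raise ValueError("correct_jumps needs at least 3 observations")
    days = series.doys
    # use true date deltas, robust to series spanning a year boundary
    dates = [o.date for o in series.observations]
    deltas = np.array(
        [(b - a).days for a, b in zip(dates, dates[1:])], dtype=float
    )
    if np.any(deltas <= 0):
        raise ValueError("dates must be strictly increasing")
    v = series.values.copy()

    for _ in range(_JUMP_PASS_LIMIT):
        changed = False
        for t in range(len(v) - 1):
            if (v[t + 1] - v[t]) / deltas[t] <= max_daily_increase:
                continue
            if t == 0:
                v[0] = v[1]
            else:
                # linear interpolation between neighbours at t-1 and t+1
                span = (dates[t + 1] - dates[t - 1]).days
                w = (dates[t] - dates[t - 1]).days / span
                v[t] = (1 - w) * v[t - 1] + w * v[t + 1]
            changed = True
        if not changed:
            break
    else:
        if np.any(np.diff(v) / deltas > max_daily_increase):
            logger.warning(
                "correct_jumps: pass limit (%d) reached for field %s",
                _JUMP_PASS_LIMIT,
                series.meta.field_id,
            )
    return series.with_values(v)


def clip_negatives(series: FieldSeries) -> FieldSeries:
    """Set negative NDVI values to zero (their magnitude is noise)."""
    return series.with_values(np.maximum(series.values, 0.0))


def _days_in_year(year: int) -> int:
    y = year
    return 366 if (y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)) else 365


def regularize(
    series: FieldSeries, window_days: int = WINDOW_DAYS, min_windows: int = 25
) -> SmoothSeries:
    """Maximum-value composite onto 36 fixed 10-day windows.

    Each window keeps the maximum observation falling inside it; empty
    windows are filled by linear interpolation between the nearest non-empty
    windows (ends held constant). A sparse year (< ``min_windows`` non-empty
    windows) is allowed with a warning.
    """
    if window_days != WINDOW_DAYS:
        raise ValueError("only the 10-day standard grid is supported")
    obs = [o for o in series.observations if o.date.year == series.year]
    if not obs:
        raise UnusableSeriesError(
            f"field {series.meta.field_id}: no observations in year {series.year}"
        )
    doys = np.array([o.doy for o in obs], dtype=float)
    vals = np.array([o.ndvi for o in obs], dtype=float)

    # window i covers DOY [1+10i, 10+10i]; the last covers 351..end of year
    idx = np.minimum((doys - 1) // window_days, N_WINDOWS - 1).astype(int)
    out = np.full(N_WINDOWS, np.nan)
    for i in range(N_WINDOWS):
        sel = idx == i
        if sel.any():
            out[i] = vals[sel].max()

    filled = np.flatnonzero(~np.isnan(out))
    if filled.size == 0:
        raise UnusableSeriesError("all windows empty")
    if filled.size < min_windows:
        logger.warning(
            "regularize: field %s has only %d/%d non-empty windows",
            series.meta.field_id,
            filled.size,
            N_WINDOWS,
        )
    all_idx = np.arange(N_WINDOWS)
    # np.interp holds end values constant outside the observed range
    out = np.interp(all_idx, filled, out[filled])
    return SmoothSeries(
        meta=series.meta,
        year=series.year,
        window_starts=WINDOW_STARTS.copy(),
        values=out,
    )


def savitzky_golay(
    regular: SmoothSeries, window: int = SG_WINDOW, polyorder: int = SG_POLYORDER
) -> SmoothSeries:
    """Savitzky–Golay smoothing on the regular grid.

    Edges are handled by evaluating the terminal polynomial fits rather
    than padding, so no spurious season starts appear at year boundaries.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if len(regular.values) < window:
        raise ValueError("series shorter than window")
    smoothed = savgol_filter(regular.values, window, polyorder, mode="interp")
    return regular.with_values(smoothed)


def preprocess(
    series: FieldSeries,
    max_daily_increase: float = MAX_DAILY_INCREASE,
    window_days: int = WINDOW_DAYS,
    sg_window: int = SG_WINDOW,
    sg_polyorder: int = SG_POLYORDER,
) -> SmoothSeries:
    """Full denoising pipeline: jumps → negatives → regularize → smooth."""
    s = correct_jumps(series, max_daily_increase=max_daily_increase)
    s = clip_negatives(s)
    r = regularize(s, window_days=window_days)
    return savitzky_golay(r, window=sg_window, polyorder=sg_polyorder)
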