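"""Rule-based cropping-intensity classification via the NDVI-ratio method.

The smoothed annual series is min–max normalized over the year
(``ratio(t) = (v(t) − min) / (max − min)``); upward/downward crossings of a
threshold τ = 0.5 mark start-of-season (SOS) and end-of-season (EOS)
events. Four rules turn events into a single/double label:

1. If the smoothed NDVI range over May–October (inclusive) is ≤ 0.3, the
   field is single-cropped (orchards and other low, flat canopies).
2. Detect SOS/EOS at the τ-crossings of the ratio.
3. An SOS with no following EOS in the year is nullified (fall-planted
   crop for next year). A leading EOS with no preceding SOS counts as one
   single-cropping cycle (e.g. winter wheat planted the prior year).
4. A growing cycle cannot be shorter than 40 days.

One retained (SOS, EOS) pair means single-cropping; two or more mean
double-cropping.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .preprocess import SmoothSeries

TAU = 0.5
RANGE_THRESHOLD = 0.3
MIN_CYCLE_DAYS = 40.0
# flat-rule window: windows whose start DOY falls on May 1 – Oct 31
# (non-leap DOY 121–304)
FLAT_RULE_DOY = (121, 304)

SINGLE = "single"
DOUBLE = "double"


class DegenerateSeriesError(ValueError):
    """The annual series is constant; the ratio is undefined."""


class EventKind(str, Enum):
    SOS = "SOS"
    EOS = "EOS"


@dataclass(frozen=True)
class RatioSeries:
    """Annually min–max normalized NDVI; attains both 0 and 1 by construction."""

    window_starts: np.ndarray
    ratios: np.ndarray


@dataclass(frozen=True)
class SeasonEvent:
    kind: EventKind
    doy: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.doy <= 366.0:
            raise ValueError(f"doy {self.doy} outside [1, 366]")


@dataclass(frozen=True)
class CropCycle:
    sos: SeasonEvent
    eos: SeasonEvent

    def __post_init__(self) -> None:
        if self.eos.doy <= self.sos.doy:
            raise ValueError("EOS must follow SOS")

    @property
    def length(self) -> float:
        return self.eos.doy - self.sos.doy


@dataclass(frozen=True)
class IntensityResult:
    """Label plus the retained cycles and the ordered trace of rules fired."""

    label: str
    cycles: tuple[CropCycle, ...]
    rule_trace: tuple[str, ...]


def ndvi_ratio(smooth: SmoothSeries) -> RatioSeries:
    """Min–max normalize the smoothed series over the full year."""
    v = smooth.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise DegenerateSeriesError("constant series: ratio undefined")
    return RatioSeries(
        window_starts=smooth.window_starts.copy(),
        ratios=(v - vmin) / (vmax - vmin),
    )


def flat_series_rule(
    smooth: SmoothSeries, range_threshold: float = RANGE_THRESHOLD
) -> str | None:
    """Rule 1: a May–October NDVI range ≤ 0.3 is a single-cropped field."""
    lo, hi = FLAT_RULE_DOY
    sel = (smooth.window_starts >= lo) & (smooth.window_starts <= hi)
    vals = smooth.values[sel]
    if vals.size == 0:
        raise ValueError("series does not cover May-October")
    if float(vals.max() - vals.min()) <= range_threshold:
        return SINGLE
    return None


def detect_events(ratio: RatioSeries, tau: float = TAU) -> list[SeasonEvent]:
    """Find SOS (upward) and EOS (downward) τ-crossings of the ratio.

    The crossing day is linearly interpolated between the bracketing grid
    points. A point lying exactly at τ counts as crossed on the side the
    series moves toward next, so plateaus at exactly τ are not
    double-counted.
    """
    r = ratio.ratios
    x = ratio.window_starts
    events: list[SeasonEvent] = []
    # state: are we above tau? exact-tau points inherit the previous state
    # until the series commits to a side.
    state: bool | None = None  # True = above
    for i in range(len(r)):
        if r[i] == tau:
            continue
        side = r[i] > tau
        if state is None:
            state = side
        elif side != state:
            # find the last point strictly on the old side to interpolate
            j = i - 1
            while r[j] == tau:
                j -= 1
            if r[j] == r[i]:
                doy = float(x[i])
            else:
                frac = (tau - r[j]) / (r[i] - r[j])
                doy = float(x[j] + frac * (x[i] - x[j]))
            kind = EventKind.SOS if side else EventKind.EOS
            events.append(SeasonEvent(kind=kind, doy=min(doy, 366.0)))
            state = side
    return events


def pair_and_filter(
    events: Sequence[SeasonEvent], min_cycle_days: float = MIN_CYCLE_DAYS
) -> tuple[list[CropCycle], list[str]]:
    """Pair SOS with the next EOS and apply rules 3–4.

    A leading EOS (fall-planted crop from the prior year, e.g. winter
    wheat) becomes a cycle with a synthetic SOS at DOY 1. An SOS with no
    following EOS is nullified. Pairs shorter than ``min_cycle_days`` are
    discarded.
    """
    trace: list[str] = []
    cycles: list[CropCycle] = []
    pending_sos: SeasonEvent | None = None
    for ev in sorted(events, key=lambda e: e.doy):
        if ev.kind is EventKind.SOS:
            if pending_sos is not None:
                trace.append("rule3a:sos_nullified")
            pending_sos = ev
        else:
            if pending_sos is None:
                # leading EOS: growth was underway at the year boundary
                trace.append("rule3b:leading_eos_cycle")
                pending_sos = SeasonEvent(kind=EventKind.SOS, doy=1.0)
            cycle = CropCycle(sos=pending_sos, eos=ev)
            if cycle.length < min_cycle_days:
                trace.append("rule4:short_cycle_discarded")
            else:
                cycles.append(cycle)
            pending_sos = None
    if pending_sos is not None and pending_sos.doy > 1.0:
        trace.append("rule3a:sos_nullified")
    return cycles, trace


def classify_ratio(
    smooth: SmoothSeries,
    tau: float = TAU,
    range_threshold: float = RANGE_THRESHOLD,
    min_cycle_days: float = MIN_CYCLE_DAYS,
) -> IntensityResult:
    """Apply the four NDVI-ratio rules to a preprocessed series.

    The label is ``double`` iff at least two cycles are retained; triple
    cropping (three retained cycles) still labels ``double`` but the cycle
    list carries the full count.
    """
    if flat_series_rule(smooth, range_threshold) is not None:
        return IntensityResult(
            label=SINGLE, cycles=(), rule_trace=("rule1:flat_range",)
        )
    try:
        ratio = ndvi_ratio(smooth)
    except DegenerateSeriesError:
        return IntensityResult(
            label=SINGLE, cycles=(), rule_trace=("degenerate:constant_series",)
        )
    events = detect_events(ratio, tau=tau)
    cycles, trace = pair_and_filter(events, min_cycle_days=min_cycle_days)
    trace = ["rule2:events_detected"] + trace
    label = DOUBLE if len(cycles) >= 2 else SINGLE
    return IntensityResult(label=label, cycles=tuple(cycles), rule_trace=tuple(trace))
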