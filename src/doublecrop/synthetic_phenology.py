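"""Synthetic crop-phenology generator with known cropping-intensity truth.

Each field-year is a sum of double-logistic greenness cycles over a bare
soil baseline, sampled at irregular ~8-day revisits with optional
cloud-induced downward spikes (occasionally driving NDVI negative),
Gaussian observation noise, timing jitter, and dropouts.

Labeling semantics: a field is double-cropped iff it carries at least two
*harvested* cycles and the second planting starts by early August
(day-of-year 219). A greenness bump starting later is a cover crop or a
fall planting for the following year, and the field counts as
single-cropped — these late bumps are exactly the confusers that defeat
threshold-based cycle counting.

Scenario kinds
--------------
``single``                  one harvested cycle
``double``                  two harvested cycles, second SOS ≤ DOY 219
``orchard_flat``            perennial canopy, low seasonal amplitude
``single_plus_cover``       one harvested cycle plus a late cover-crop bump
``single_plus_fall_planting`` one harvested cycle plus a rising fall tail
                            that does not senesce within the year
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .timeseries_io import FieldMeta, FieldSeries, Observation

SINGLE = "single"
DOUBLE = "double"
EARLY_AUGUST_DOY = 219  # Aug 7 in a non-leap year
DEFAULT_YEAR = 2017

SCENARIO_KINDS = (
    "single",
    "double",
    "orchard_flat",
    "single_plus_cover",
    "single_plus_fall_planting",
)

# crops drawn per scenario kind: some double-heavy, some never double
DEFAULT_CROP_CATALOG: dict[str, list[str]] = {
    "single": ["wheat", "potato", "field_corn", "timothy"],
    "double": ["buckwheat", "sweet_corn", "green_pea", "sudangrass"],
    "orchard_flat": ["apple", "cherry"],
    "single_plus_cover": ["potato", "wheat", "field_corn"],
    "single_plus_fall_planting": ["wheat", "timothy"],
}


@dataclass(frozen=True)
class CycleSpec:
    """One greenness cycle: double-logistic rise and fall.

    ``rise_rate``/``fall_rate`` are logistic steepness per day; the default
    0.10/day gives a 10–90% green-up of ~44 days, consistent with planting
    to peak canopy taking well over a month. ``harvested`` distinguishes a
    production crop from a cover-crop/fall-planting bump for labeling.
    """

    sos_doy: float
    length: float
    peak_ndvi: float
    base_ndvi: float = 0.08
    rise_rate: float = 0.10
    fall_rate: float = 0.10
    harvested: bool = True

    def __post_init__(self) -> None:
        if self.peak_ndvi <= self.base_ndvi:
            raise ValueError("peak must exceed base")
        if not 0.2 < self.peak_ndvi <= 1.0:
            raise ValueError("peak_ndvi must be in (0.2, 1]")
        if not 0.0 <= self.base_ndvi < 0.3:
            raise ValueError("base_ndvi must be in [0, 0.3)")

    @property
    def eos_doy(self) -> float:
        return self.sos_doy + self.length


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise model; all-zero means a clean series."""

    cloud_prob: float = 0.0
    spike_depth: tuple[float, float] = (0.15, 0.9)  # uniform subtraction
    gaussian_sd: float = 0.0
    dropout_prob: float = 0.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Irregular satellite revisit: nominal 8-day cadence with jitter."""

    start_doy: float = 3.0
    revisit_days: float = 8.0
    jitter_days: float = 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str
    cycles: tuple[CycleSpec, ...]
    acquisition: AcquisitionSpec = AcquisitionSpec()
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        harvested = [c for c in self.cycles if c.harvested]
        if self.kind == "double":
            if len(harvested) < 2 or harvested[1].sos_doy > EARLY_AUGUST_DOY:
                raise ValueError(
                    "double scenario needs 2 harvested cycles, second SOS <= 219"
                )
        if self.kind == "single_plus_cover":
            bumps = [c for c in self.cycles if not c.harvested]
            if not bumps or min(b.sos_doy for b in bumps) <= EARLY_AUGUST_DOY:
                raise ValueError("cover bump must start after DOY 219")

    @property
    def label(self) -> str:
        """Truth label: pure function of the cycle structure."""
        harvested = sorted(
            (c for c in self.cycles if c.harvested), key=lambda c: c.sos_doy
        )
        if len(harvested) >= 2 and harvested[1].sos_doy <= EARLY_AUGUST_DOY:
            return DOUBLE
        return SINGLE


@dataclass(frozen=True)
class TruthRecord:
    field_id: str
    label: str
    cycle_count: int
    scenario: str
    crop: str
    area: float


def _raw_curve(spec: CycleSpec, t: np.ndarray) -> np.ndarray:
    """Unnormalized product of rise and fall logistics."""
    mid_rise = spec.sos_doy + 0.2 * spec.length
    mid_fall = spec.sos_doy + 0.8 * spec.length
    rise = 1.0 / (1.0 + np.exp(-spec.rise_rate * (t - mid_rise)))
    fall = 1.0 / (1.0 + np.exp(spec.fall_rate * (t - mid_fall)))
    return rise * fall


def cycle_curve(spec: CycleSpec, doys: Sequence[float]) -> np.ndarray:
    """Evaluate one cycle at arbitrary days-of-year.

    The double-logistic product is rescaled so its annual maximum equals
    ``peak_ndvi`` exactly (the raw product peaks slightly below 1).
    """
    t = np.asarray(doys, dtype=float)
    dense = np.arange(1.0, 367.0)
    scale = _raw_curve(spec, dense).max()
    g = _raw_curve(spec, t) / scale
    return spec.base_ndvi + (spec.peak_ndvi - spec.base_ndvi) * g


def _scenario_curve(spec: ScenarioSpec, doys: np.ndarray) -> np.ndarray:
    """Sum of cycle contributions above a shared baseline."""
    base = max(c.base_ndvi for c in spec.cycles)
    total = np.full(len(doys), base)
    for c in spec.cycles:
        total = total + (cycle_curve(c, doys) - c.base_ndvi)
    return np.clip(total, -1.0, 1.0)


def generate_field(
    spec: ScenarioSpec,
    field_id: str = "F0",
    crop: str = "unknown",
    area: float = 40.0,
    year: int = DEFAULT_YEAR,
    county: str = "synthetic",
    irrigation: str = "sprinkler",
) -> tuple[FieldSeries, TruthRecord]:
    """Sample one field-year from a scenario; deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    acq = spec.acquisition
    doys = np.arange(acq.start_doy, 366.0, acq.revisit_days)
    if acq.jitter_days > 0:
        doys = doys + rng.uniform(-acq.jitter_days, acq.jitter_days, size=len(doys))
    doys = np.unique(np.clip(np.round(doys), 1, 365).astype(int))
    if spec.noise.dropout_prob > 0:
        keep = rng.random(len(doys)) >= spec.noise.dropout_prob
        if not keep.any():
            keep[0] = True
        doys = doys[keep]

    values = _scenario_curve(spec, doys.astype(float))
    if spec.noise.gaussian_sd > 0:
        values = values + rng.normal(0.0, spec.noise.gaussian_sd, size=len(values))
    if spec.noise.cloud_prob > 0:
        cloudy = rng.random(len(values)) < spec.noise.cloud_prob
        lo, hi = spec.noise.spike_depth
        depth = rng.uniform(lo, hi, size=len(values))
        values = np.where(cloudy, values - depth, values)
    values = np.clip(values, -1.0, 1.0)

    jan1 = _dt.date(year, 1, 1)
    obs = tuple(
        Observation(jan1 + _dt.timedelta(days=int(d) - 1), float(v))
        for d, v in zip(doys, values)
    )
    meta = FieldMeta(
        field_id=field_id,
        crop=crop,
        irrigation=irrigation,
        county=county,
        area=area,
        survey_year=year,
    )
    harvested = [c for c in spec.cycles if c.harvested]
    truth = TruthRecord(
        field_id=field_id,
        label=spec.label,
        cycle_count=len(harvested),
        scenario=spec.kind,
        crop=crop,
        area=area,
    )
    return FieldSeries(meta=meta, year=year, observations=obs), truth


# --------------------------------------------------------------------------
# Scenario templates

def _draw_cycles(kind: str, rng: np.random.Generator) -> tuple[CycleSpec, ...]:
    base = rng.uniform(0.05, 0.14)
    if kind == "orchard_flat":
        # perennial canopy: moderate NDVI, low seasonal amplitude
        base_o = rng.uniform(0.24, 0.29)
        return (
            CycleSpec(
                sos_doy=rng.uniform(60, 90),
                length=rng.uniform(200, 240),
                peak_ndvi=base_o + rng.uniform(0.12, 0.20),
                base_ndvi=base_o,
                rise_rate=0.05,
                fall_rate=0.05,
            ),
        )
    if kind == "single":
        return (
            CycleSpec(
                sos_doy=rng.uniform(100, 150),
                length=rng.uniform(95, 140),
                peak_ndvi=rng.uniform(0.72, 0.9),
                base_ndvi=base,
            ),
        )
    if kind == "double":
        sos1 = rng.uniform(95, 105)
        len1 = rng.uniform(78, 85)
        gap = rng.uniform(14, 22)
        sos2 = sos1 + len1 + gap  # at most 212, before early August
        len2 = rng.uniform(78, 85)
        # harvest drops NDVI abruptly (crop is cut, not left to senesce)
        return (
            CycleSpec(sos_doy=sos1, length=len1,
                      peak_ndvi=rng.uniform(0.80, 0.90), base_ndvi=base,
                      fall_rate=0.16),
            CycleSpec(sos_doy=sos2, length=len2,
                      peak_ndvi=rng.uniform(0.80, 0.90), base_ndvi=base,
                      fall_rate=0.16),
        )
    if kind == "single_plus_cover":
        main = CycleSpec(
            sos_doy=rng.uniform(100, 130),
            length=rng.uniform(75, 95),
            peak_ndvi=rng.uniform(0.72, 0.9),
            base_ndvi=base,
        )
        bump = CycleSpec(
            sos_doy=rng.uniform(235, 260),
            length=rng.uniform(65, 80),
            peak_ndvi=rng.uniform(0.55, 0.75),
            base_ndvi=base,
            harvested=False,
        )
        return (main, bump)
    if kind == "single_plus_fall_planting":
        main = CycleSpec(
            sos_doy=rng.uniform(100, 140),
            length=rng.uniform(85, 110),
            peak_ndvi=rng.uniform(0.72, 0.9),
            base_ndvi=base,
        )
        # fall planting greens up toward the year boundary, no senescence
        tail = CycleSpec(
            sos_doy=rng.uniform(270, 295),
            length=150.0,
            peak_ndvi=rng.uniform(0.5, 0.7),
            base_ndvi=base,
            harvested=False,
        )
        return (main, tail)
    raise ValueError(f"unknown scenario kind {kind!r}")


def generate_dataset(
    n_fields: int,
    class_mix: Mapping[str, float],
    crop_catalog: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    noise: NoiseSpec = NoiseSpec(),
    jitter_days: float = 0.0,
    year: int = DEFAULT_YEAR,
) -> tuple[list[FieldSeries], list[TruthRecord]]:
    """Draw ``n_fields`` field-years with scenario kinds per ``class_mix``.

    Crop labels are drawn per scenario kind from the catalog, so some crops
    are double-heavy (buckwheat-like) and some never double (orchards).
    Areas are log-uniform in [5, 500] acres so the 10-acre filter has work
    to do. Deterministic per seed.
    """
    mix = dict(class_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    unknown = set(mix) - set(SCENARIO_KINDS)
    if unknown:
        raise ValueError(f"unknown scenario kinds in mix: {sorted(unknown)}")
    catalog = {**DEFAULT_CROP_CATALOG, **(crop_catalog or {})}
    rng = np.random.default_rng(seed)
    kinds = rng.choice(list(mix), size=n_fields, p=list(mix.values()))

    series: list[FieldSeries] = []
    truths: list[TruthRecord] = []
    for i, kind in enumerate(kinds):
        crop = str(rng.choice(list(catalog[kind])))
        area = float(np.exp(rng.uniform(np.log(5.0), np.log(500.0))))
        acq = AcquisitionSpec(
            start_doy=float(rng.integers(1, 9)),
            jitter_days=jitter_days,
        )
        spec = ScenarioSpec(
            kind=str(kind),
            cycles=_draw_cycles(str(kind), rng),
            acquisition=acq,
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fs, tr = generate_field(
            spec, field_id=f"S{i:05d}", crop=crop, area=area, year=year
        )
        series.append(fs)
        truths.append(tr)
    return series, truths


NOISY_NOISE = NoiseSpec(cloud_prob=0.15, spike_depth=(0.15, 0.9),
                        gaussian_sd=0.02, dropout_prob=0.1)

BATTERY_SPECS: dict[str, dict] = {
    # noise-free, no confusers: the ratio rules recover every label
    "CLEAN": dict(
        n_fields=300,
        class_mix={"single": 0.55, "double": 0.30, "orchard_flat": 0.15},
        noise=NoiseSpec(),
        jitter_days=0.0,
    ),
    # clouds, jitter, dropouts; all scenario kinds
    "NOISY": dict(
        n_fields=400,
        class_mix={
            "single": 0.40,
            "double": 0.20,
            "orchard_flat": 0.15,
            "single_plus_cover": 0.15,
            "single_plus_fall_planting": 0.10,
        },
        noise=NOISY_NOISE,
        jitter_days=2.0,
    ),
    # rich in late-bump confusers that defeat threshold cycle counting
    "CONFUSER": dict(
        n_fields=400,
        class_mix={
            "single": 0.25,
            "double": 0.15,
            "single_plus_cover": 0.35,
            "single_plus_fall_planting": 0.25,
        },
        noise=NOISY_NOISE,
        jitter_days=2.0,
    ),
    # double-cropped a minority of the landscape, ~12% of area
    "IMBALANCED": dict(
        n_fields=400,
        class_mix={
            "single": 0.50,
            "double": 0.12,
            "orchard_flat": 0.18,
            "single_plus_cover": 0.12,
            "single_plus_fall_planting": 0.08,
        },
        noise=NOISY_NOISE,
        jitter_days=2.0,
    ),
}


def default_battery(
    seed: int, names: Sequence[str] | None = None
) -> dict[str, tuple[list[FieldSeries], list[TruthRecord]]]:
    """The standard named datasets (CLEAN, NOISY, CONFUSER, IMBALANCED).

    Each battery gets a sub-seed derived from ``seed``; regeneration from
    the same seed is bit-identical.
    """
    out = {}
    for i, (name, kw) in enumerate(BATTERY_SPECS.items()):
        if names is not None and name not in names:
            continue
        out[name] = generate_dataset(seed=(seed * 7919 + i) % 2**31, **kw)
    return out


def truth_table(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Truth records as a DataFrame (one row per field)."""
    return pd.DataFrame(
        [
            (t.field_id, t.label, t.cycle_count, t.scenario, t.crop, t.area)
            for t in truths
        ],
        columns=["field_id", "label", "cycle_count", "scenario", "crop", "area"],
    )
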