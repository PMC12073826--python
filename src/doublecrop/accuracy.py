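"""Map-accuracy assessment for the binary single/double classification.

Count-based overall (OA), user's (UA) and producer's (PA) accuracies with
standard errors that respect the crop-stratified sampling design, plus an
area-proportional confusion matrix (no SEs — there is no accepted
methodology for object-based designs) and crop-wise / regional
double-cropped acreage summaries.

Stratified estimator
--------------------
With strata h = 1..H, population weights W_h (population stratum size over
population total; sample proportions when population sizes are not given),
and per-record indicators, each accuracy is a combined ratio

    R = Σ_h W_h ȳ_h / Σ_h W_h x̄_h

where for OA x ≡ 1 and y = 1{correct}; for UA of the double class
x = 1{predicted double}, y = 1{predicted double and correct}; for PA
x = 1{truth double}. The variance uses the standard linearization
d_i = y_i − R·x_i:

    Var(R) ≈ (1 / X̂²) Σ_h W_h² (1 − n_h/N_h) s²_{d,h} / n_h

with X̂ = Σ_h W_h x̄_h, s²_{d,h} the within-stratum sample variance of d
(denominator n_h − 1), and the finite-population correction applied only
when population sizes are supplied. With a single stratum and x ≡ 1 this
collapses to the simple-random-sampling form sqrt(p(1−p)/(n−1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SINGLE = "single"
DOUBLE = "double"
_LABELS = (SINGLE, DOUBLE)


@dataclass
class ConfusionSummary:
    """Overall and per-stratum 2×2 tallies, indexed (truth, predicted)."""

    counts: np.ndarray                      # shape (2, 2), rows = truth
    per_stratum: dict[str, np.ndarray]
    truth: np.ndarray
    predicted: np.ndarray
    strata: np.ndarray
    areas: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class AccuracyReport:
    """Point estimates (None when the denominator is empty) and their SEs."""

    oa: float
    ua_double: float | None
    pa_double: float | None
    se_oa: float | None = None
    se_ua: float | None = None
    se_pa: float | None = None
    area_matrix: np.ndarray | None = None
    n: int = 0


def _li(label: str) -> int:
    try:
        return _LABELS.index(label)
    except ValueError:
        raise ValueError(f"label must be one of {_LABELS}, got {label!r}") from None


def confusion(
    truth: Sequence[str],
    predicted: Sequence[str],
    strata: Sequence[str] | None = None,
    areas: Sequence[float] | None = None,
) -> ConfusionSummary:
    """Tally the 2×2 confusion matrix, overall and per crop stratum."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted length mismatch")
    strata_arr = (
        np.asarray(strata, dtype=object)
        if strata is not None
        else np.full(len(truth), "all", dtype=object)
    )
    if len(strata_arr) != len(truth):
        raise ValueError("strata length mismatch")
    areas_arr = None
    if areas is not None:
        areas_arr = np.asarray(areas, dtype=float)
        if len(areas_arr) != len(truth):
            raise ValueError("areas length mismatch")

    counts = np.zeros((2, 2))
    per_stratum: dict[str, np.ndarray] = {}
    for t, p, s in zip(truth, predicted, strata_arr):
        i, j = _li(t), _li(p)
        counts[i, j] += 1
        per_stratum.setdefault(s, np.zeros((2, 2)))[i, j] += 1
    return ConfusionSummary(
        counts=counts,
        per_stratum=per_stratum,
        truth=truth,
        predicted=predicted,
        strata=strata_arr,
        areas=areas_arr,
    )


def accuracy_metrics(summary: ConfusionSummary) -> AccuracyReport:
    """Pooled OA, UA(double), PA(double); undefined ratios come back None."""
    c = summary.counts
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    oa = float(np.trace(c) / n)
    pred_double = c[:, 1].sum()
    truth_double = c[1, :].sum()
    ua = float(c[1, 1] / pred_double) if pred_double > 0 else None
    pa = float(c[1, 1] / truth_double) if truth_double > 0 else None
    return AccuracyReport(oa=oa, ua_double=ua, pa_double=pa, n=int(n))


def _metric_indicators(summary: ConfusionSummary, metric: str) -> tuple[np.ndarray, np.ndarray]:
    correct = summary.truth == summary.predicted
    if metric == "oa":
        x = np.ones(len(correct))
        y = correct.astype(float)
    elif metric == "ua":
        x = (summary.predicted == DOUBLE).astype(float)
        y = x * correct
    elif metric == "pa":
        x = (summary.truth == DOUBLE).astype(float)
        y = x * correct
    else:
        raise ValueError(metric)
    return y, x


def _combined_ratio(
    summary: ConfusionSummary,
    metric: str,
    pop_sizes: Mapping[str, float] | None,
) -> tuple[float | None, float | None]:
    y, x = _metric_indicators(summary, metric)
    strata = summary.strata
    names = sorted(set(strata))
    n_h = {s: int(np.sum(strata == s)) for s in names}
    if pop_sizes is not None:
        missing = set(names) - set(pop_sizes)
        if missing:
            raise ValueError(f"population sizes missing for strata: {sorted(missing)}")
        N = sum(pop_sizes[s] for s in names)
        W = {s: pop_sizes[s] / N for s in names}
    else:
        W = {s: n_h[s] / len(strata) for s in names}

    Y = sum(W[s] * y[strata == s].mean() for s in names)
    X = sum(W[s] * x[strata == s].mean() for s in names)
    if X == 0:
        return None, None
    R = Y / X

    var = 0.0
    for s in names:
        sel = strata == s
        nh = n_h[s]
        if nh < 2:
            # a singleton stratum contributes no estimable variance
            continue
        d = y[sel] - R * x[sel]
        s2 = d.var(ddof=1)
        fpc = 1.0 - nh / pop_sizes[s] if pop_sizes is not None else 1.0
        var += W[s] ** 2 * max(fpc, 0.0) * s2 / nh
    return R, math.sqrt(var) / X


def stratified_standard_errors(
    summary: ConfusionSummary,
    population_sizes: Mapping[str, float] | None = None,
) -> AccuracyReport:
    """OA/UA/PA with design-based standard errors (see module docstring).

    ``population_sizes`` maps each stratum to its population count; when
    omitted, sample proportions act as weights and no finite-population
    correction is applied.
    """
    point = accuracy_metrics(summary)
    oa, se_oa = _combined_ratio(summary, "oa", population_sizes)
    ua, se_ua = _combined_ratio(summary, "ua", population_sizes)
    pa, se_pa = _combined_ratio(summary, "pa", population_sizes)
    return AccuracyReport(
        oa=oa if oa is not None else point.oa,
        ua_double=ua,
        pa_double=pa,
        se_oa=se_oa,
        se_ua=se_ua,
        se_pa=se_pa,
        n=point.n,
    )


def area_matrix(summary: ConfusionSummary) -> np.ndarray:
    """Area-proportional 2×2 confusion matrix (cells sum to 1)."""
    if summary.areas is None:
        raise ValueError("summary carries no areas")
    out = np.zeros((2, 2))
    for t, p, a in zip(summary.truth, summary.predicted, summary.areas):
        out[_li(t), _li(p)] += a
    total = out.sum()
    if total == 0:
        raise ValueError("total area is zero")
    return out / total


def per_crop_double_fraction(
    predictions: Sequence[str],
    crops: Sequence[str],
    areas: Sequence[float],
) -> pd.Series:
    """Percent of each crop's acreage predicted double-cropped."""
    df = pd.DataFrame({"crop": crops, "pred": predictions, "area": areas})
    double_acres = df[df["pred"] == DOUBLE].groupby("crop")["area"].sum()
    total_acres = df.groupby("crop")["area"].sum()
    frac = 100.0 * double_acres.reindex(total_acres.index).fillna(0.0) / total_acres
    frac.name = "pct_acres_double"
    return frac


def regional_summary(
    predictions: Sequence[str],
    regions: Sequence[str],
    areas: Sequence[float],
) -> pd.Series:
    """Percent of each region's acreage predicted double-cropped."""
    df = pd.DataFrame({"region": regions, "pred": predictions, "area": areas})
    double_acres = df[df["pred"] == DOUBLE].groupby("region")["area"].sum()
    total_acres = df.groupby("region")["area"].sum()
    frac = 100.0 * double_acres.reindex(total_acres.index).fillna(0.0) / total_acres
    frac.name = "pct_acres_double"
    return frac
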