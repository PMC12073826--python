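# Methods

## Problem and scope

The package classifies each agricultural field-year as single- or
double-cropped from its annual NDVI time series. The analysis is
object-based: NDVI is assumed to be already averaged over the pixels of a
field polygon, so the unit of work is one sequence of dated observations
per field per calendar year at a nominal ~8-day revisit (two staggered
16-day satellite missions). Image acquisition, cloud masking, and
pixel-to-field aggregation are upstream of this package.

The scientific difficulty is not the textbook case of two clean greenness
peaks. In crop-diverse irrigated regions, late-season cover crops and
fall-planted crops for the following year produce a *second green-up* that
a threshold rule cannot distinguish from a second harvested crop. The
convention implemented here is that only a second crop **planted by early
August (day-of-year 219) and harvested within the year** counts as
double-cropping; later green-ups are single-cropping. This timing rule is
encoded in the synthetic generator's labels, not in the rule-based
classifier — which is precisely why the rule-based classifier over-predicts
doubles and the trained models do not.

## Denoising pipeline

Steps are applied in this fixed order; the full pipeline is deterministic.

1. **Jump repair** (`correct_jumps`, cap 0.018 NDVI/day). Canopy cannot
   green up faster than ~0.018/day (this forces planting-to-peak to take at
   least about a month), so a faster observed rise means the *earlier*
   observation was depressed by undetected cloud. That observation is
   replaced by linear interpolation between its neighbours (the first point
   takes its right neighbour's value). Because one repair can expose
   another violation, sweeps repeat to convergence with a pass limit of 20;
   for cloud-spike noise on phenologically plausible curves convergence is
   reached well inside the limit. A series whose *endpoint-to-endpoint*
   rise genuinely exceeds the cap (not a crop signal) cannot be fully
   repaired; the function then returns the best achievable state with a
   warning.
2. **Negative clipping** (`clip_negatives`). Negative NDVI means no
   vegetation; its magnitude is noise. Left in place, a single −0.9 spike
   would inflate the ratio denominator and lift the normalized mid-season
   trough, hiding the harvest/replant dip.
3. **Regularization** (`regularize`). Maximum-value compositing onto 36
   fixed 10-day windows anchored at Jan 1 (starts DOY 1, 11, …, 351; the
   last window absorbs the year end). The maximum is used because
   atmospheric contamination only lowers NDVI. Empty windows are filled by
   linear interpolation between the nearest occupied windows, with end
   values held constant; a year with fewer than 25 occupied windows is
   processed with a warning. The 36-point grid also fixes the feature
   length for the classifiers.
4. **Savitzky–Golay smoothing** (window 7, polynomial order 3), backed by
   `scipy.signal.savgol_filter(mode="interp")`: edges are handled by
   evaluating the terminal polynomial fits rather than padding, because
   reflective padding fabricates spurious season starts at year boundaries.
   SG reproduces any cubic exactly, may overshoot slightly (values are
   contracted to lie in [−0.05, 1.05]), and the output is deliberately
   **not** re-clipped, since re-clipping would distort the ratio
   denominator.

## Rule-based NDVI-ratio classifier

`ratio(t) = (v(t) − min) / (max − min)` with min/max over the **full**
smoothed year (not May–October), and τ = 0.5.

* **Rule 1 (flat range).** If the smoothed May–October (inclusive) range is
  ≤ 0.3 the field is single-cropped — orchards and other perennial canopies
  are low and flat. This rule short-circuits the rest.
* **Rule 2 (events).** SOS at each upward τ-crossing, EOS at each downward
  one. The crossing day is linearly interpolated between the bracketing
  grid points. A point exactly at τ is counted as crossed on the side the
  series next commits to, so a plateau at exactly 0.5 is one crossing, not
  several.
* **Rule 3.** An SOS with no following EOS in the year is nullified
  (fall-planted crop for next year). A leading EOS with no preceding SOS is
  a crop planted the previous year (winter wheat); it becomes a cycle with
  a synthetic SOS at DOY 1, and its length is measured from there. A lone
  EOS followed by a later full cycle therefore yields two cycles — the
  fall-wheat-then-buckwheat succession.
* **Rule 4.** Cycles shorter than 40 days are discarded.

Two or more retained cycles ⇒ double; otherwise single (three cycles are
collapsed to "double" — the label set is binary — but the full cycle list is
reported). Each decision carries a `rule_trace` naming the rules that
fired.

## Trained classifiers

Feature vector: the 36 smoothed NDVI values in window order, unscaled.
Models: RBF SVM, random forest, and kNN with dynamic time warping (DTW)
distance. DTW uses absolute-difference local cost with unit
match/insert/delete steps and an optional Sakoe–Chiba band; it absorbs
planting-date shifts between fields that defeat lockstep (Euclidean)
distance. The DTW dynamic program is implemented in the package
(numba-accelerated when available, with an identical pure-numpy fallback)
and is validated in the tests against an exhaustive enumeration of warping
paths.

Training protocol:

* **Splitting**: crop-stratified 80/20 train/test; `round(0.2·n)` of each
  crop stratum to test, singleton strata to train; deterministic per seed.
* **Imbalance**: the minority (double) class is oversampled with
  replacement to 50% of the majority size. Oversampling happens **inside
  each CV training fold only** — duplicated minority records leaking into a
  validation fold would score themselves and inflate CV accuracy — and
  again on the full training set for the final refit. Validation folds and
  the test set keep the native class balance.
* **Selection**: 5-fold class-stratified CV over small standard grids
  (SVM: C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.1}; RF: trees ∈
  {100, 300} × depth ∈ {∞, 10}; kNN: k ∈ {1, 3, 5, 7}), scored by overall
  accuracy, ties to the first grid entry. For kNN the train×train DTW
  matrix is computed once and sliced per fold, so prediction cost is
  independent of the grid.

Models serialize to a versioned joblib container embedding the chosen
hyperparameters, seed, and CV table; a reloaded model predicts
identically. `render_series_image` provides a deterministic grayscale
rasterization of a series as the input adapter for an external image
classifier (e.g. a transfer-learned CNN); training such a model is outside
the package and no deep-learning dependency is required.

## Accuracy assessment

Count-based OA, and UA/PA for the double class (UA: fraction of predicted
doubles that are truly double; PA: fraction of true doubles predicted
double). Standard errors follow the stratified combined-ratio estimator
with crops as strata: with population stratum weights `W_h`, each accuracy
is `R = Σ W_h ȳ_h / Σ W_h x̄_h`, and the variance uses the linearization
`d_i = y_i − R·x_i` with within-stratum sample variances (denominator
n_h − 1), a finite-population correction only when population stratum sizes
are supplied, and zero contribution (with a warning semantics documented in
code) from strata with fewer than two samples. With one stratum this
collapses to the simple-random-sampling form `sqrt(p(1−p)/(n−1))`. The
exact design-vs-poststratified estimator variant used in the map-accuracy
literature is not uniquely determined; the combined-ratio form implemented
here is the standard design-consistent choice and is exercised by
closed-form tests. Undefined ratios (empty denominator) are reported as
not-available, never as 0.

The area-proportional confusion matrix divides each cell's acreage by the
total; no SEs are produced for it, as there is no accepted methodology for
object-based (per-polygon) designs. Per-crop and per-region summaries
report the percent of acreage labeled double, acre-weighted.

Fields smaller than 10 acres are removed before analysis (strictly smaller:
a 10.0-acre field stays), since a small field averages too few 30 m pixels
for a stable signal.

## Synthetic generator

Each cycle is the product of a rising and a falling logistic, rescaled so
its annual maximum equals `peak_ndvi` exactly; a field curve is the shared
baseline plus the sum of cycle contributions. Default steepness 0.10/day
puts the 10–90% green-up at ~44 days, consistent with the 0.018/day cap;
harvested cycles in double scenarios fall at 0.16/day because harvest cuts
the canopy rather than waiting for senescence — this also keeps the
harvest/replant trough resolvable at an 8-day revisit (the generator
guarantees ≥ 5 days, in practice ≥ 14, between first-cycle EOS and
second-cycle SOS). Sampling: nominal 8-day revisit with a random start
day, optional ±2-day jitter and dropouts. Noise: Gaussian observation
error, plus cloud spikes that only *subtract* (floor −1), matching the
physics of contamination. Truth labels are a pure function of the cycle
structure — never of the noise draws.

Parameter defaults (annual-crop peaks 0.72–0.9, bases 0.05–0.14, single
cycles 95–140 days, double cycles 78–85 days each with peaks 0.80–0.90,
cover bumps starting DOY 235–260 with peaks 0.55–0.75, orchard amplitude
≤ 0.2 over a 0.24–0.29 base) were chosen once as phenologically plausible
for an arid irrigated region with a hot summer; areas are log-uniform in
[5, 500] acres so the 10-acre filter is exercised.

Standard batteries (regenerated bit-identically from a seed):

* **CLEAN** (n = 300): no noise, no confusers — singles, doubles, orchards.
  Constructed so every true cycle is comfortably above τ after
  normalization and ≥ 40 days wide; the ratio rules recover 100% of labels.
* **NOISY** (n = 400): clouds, jitter, dropouts; all five scenario kinds.
* **CONFUSER** (n = 400): rich in cover-crop and fall-planting confusers.
* **IMBALANCED** (n = 400): double-cropping ≈ 12% of acreage, the minority
  prevalence regime the method targets.

**What the generator does not emulate**: mixed pixels and field-boundary
effects, crop-specific spectral saturation, multi-cut hay signatures
(alfalfa's 3–4 cuttings per season), snow contamination, sensor
inter-calibration bias, and spatial correlation between neighbouring
fields. Passing tests on these batteries therefore demonstrates the
internal correctness and the *direction* of the rule-based method's failure
(over-predicting doubles on late green-ups), not real-world accuracy
levels: real expert-labeled data are messier, and trained-model accuracies
near 100% on the batteries should be read as separability of the synthetic
scenarios, not as a field-ready error rate.

## Numerical choices and degenerate inputs

* A constant annual series makes the ratio undefined; it is classified
  single with an explicit degeneracy trace.
* Duplicate (field, date) rows average with a warning (same-day overlap of
  two satellite missions is plausible); unparseable rows raise listing the
  offending rows.
* τ-crossing dates are linearly interpolated, not snapped to the 10-day
  grid.
* The flat-range rule uses smoothed values (windows whose start DOY falls
  in May 1 – Oct 31).
* Problem sizes in the test battery (300–400 fields; 500 DTW oracle pairs
  of length ≤ 6; 100 random cubics) were chosen so that the whole
  validation suite demonstrates each property at convincing scale while
  remaining a routine desk-side run.

## Known limitations

* The binary label set collapses triple-cropping into "double".
* Jump repair cannot fix a series whose genuine endpoints rise faster than
  the cap (not a crop signal); it warns and returns the best state.
* Area-based accuracy has no standard errors (no accepted object-based
  methodology).
* The kNN-DTW model stores its (oversampled) training matrix; memory grows
  with training size.
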