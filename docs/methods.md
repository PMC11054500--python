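# Methods

This note records the models implemented in `walk6mwt`, the parameter
choices that matter, and what the simulator-based validation does and
does not establish.

## Geodesy and frames

Distances are great-circle (haversine) on a sphere of radius
6 371 000 m; at walk scale (< 2 km) the spherical-vs-ellipsoidal error is
far below GNSS noise. Planar computations (tracking filters, turning
angles) use an equirectangular east-north projection about the first fix
of the trace, which agrees with the haversine metric to better than
0.1 % over such extents. Timestamps are seconds (float); all internal
time deltas are seconds.

## Exclusion filters

Six rules run in a fixed order per sample; a removed sample is tagged
with the *first* rule it fails (the order affects counts only, never the
kept set). Pairwise rules compare against the last **kept** sample, so a
single bad fix cannot shield the next one. Defaults: accuracy radius
≤ 25 m (R2), acceleration magnitude ≥ 0.5 m/s² (R3, skipped when inertial
data are absent), step count must advance (R4, likewise skipped), Δt > 0
(R5), implied speed ≤ 5 m/s (R6). R1 removes fixes without altitude,
which phones produce when positioning from WiFi/cell rather than
satellites. An optional, default-off leading trim reproduces the
recording app's start condition (wait for one fix with accuracy < 15 m).

## Resampling

The tracking filters assume a constant 1 Hz rate, so filtered traces are
resampled onto the integer-second grid: positions and altitude are
interpolated linearly across gaps up to 5 s and held (padded) across
longer gaps; the accuracy radius at a grid point is the pessimistic
maximum of its two bracketing raw values; heading is recomputed from
consecutive grid positions (raw headings cannot be interpolated across
the 0/360 wrap) and speed as grid-step distance per second.

## Distance estimators

All six integrate the distance between consecutive estimated positions
and return 0 below two usable samples.

* **baseline** — direct sum over fixes. Correlated noise adds length at
  every step, so this estimator is biased upward on noisy traces; it
  exists as the reference point.
* **qss** — tumbling 5 s windows aligned to the first timestamp, one
  lowest-accuracy-radius fix per window, accepted sequentially only when
  time advances, implied speed ≤ 2 m/s, and (when step data exist) the
  step count changed. Sub-sampling a straight path is lossless (chords
  of a line add up exactly), but chords under-measure arcs, so QSS
  systematically under-estimates tight circular paths.
* **alphabeta** — per-axis steady-state tracker. Gains derive from the
  tracking index λ = σ_w T²/σ_n via r = (4 + λ − √(8λ + λ²))/4,
  α = 1 − r², β = 2(2 − α) − 4√(1 − α); λ = 1 gives (α, β) =
  (0.75, 0.5) and the gains grow monotonically with λ. σ_w is the
  sample's reported accuracy radius (floored at 0.01 m — at exactly zero
  the gains vanish and the filter freezes; the floor is disableable) and
  σ_n is a dimensionless smoothing constant, default 3. Both the
  position correction and the velocity update use the prediction
  residual of the current step.
* **kalman1d** — independent (position, velocity) filters per planar
  axis: A = [[1, T], [0, 1]], Q = outer((6 m, 2 m/s)) =
  [[36, 12], [12, 4]], scalar R = accuracy² per step. The initial state
  is the first fix at zero velocity with P₀ = diag(acc₀², σ_speed²).
* **kalman2d** — one joint constant-acceleration filter over
  (x, y, vx, vy, ax, ay). The process covariance extends the outer-product
  construction with a third scale σ_acc = 1 m/s² per axis and no
  cross-axis correlation; R = diag(acc², acc²). The acceleration scale is
  a design choice (nothing pins it down); it is configurable.
* **kalmansmooth** — forward filter plus fixed-interval RTS backward
  pass on the state (lat, lon, speed) with identity transition (random
  walk) and fixed observation covariance diag(1e-8 deg², 1e-8 deg²,
  1e4 (m/s)²) — positions in degrees are trusted, the speed channel is
  effectively ignored. This estimator keeps degree-valued coordinates
  because its fixed observation covariance is stated in degrees, unlike
  the other filters which run in meters. The process covariance is not
  published anywhere; it is chosen as diag((1e-4 deg)², (1e-4 deg)²,
  (0.1 m/s)²) so that the coordinate random walk (≈ 11 m/s scale) is
  commensurate with the observation covariance and the smoothed track
  follows a zero-noise walk to well within 2 %; smaller values
  over-smooth and clip corners. Input is resampled/padded to 1 Hz
  internally.

Covariances are symmetrized (P ← (P + Pᵀ)/2) after every update, and
gains use a pseudo-inverse so R = 0 (perfectly trusted measurements) is
handled exactly.

## Agreement statistics

Signed error is estimate − reference (the sign convention is ours; the
limits of agreement are symmetric under it). LOA = mean ± 1.96 sd with
the sample (n−1) standard deviation. The error band threshold defaults
to 30 m, a conservative minimal-detectable-change value for the 6MWD;
the boundary value itself is classified "low" (the strict inequalities
in the band's definition leave 30 m exactly unassigned).

## Quality features

The 7 × 7 grid plus three summative features gives exactly 52 scalars
(the alternative reading, 52 grid + 3 = 55, is arithmetically
inconsistent with a 7 × 7 grid and is not used). Conventions chosen
where the definitions were open:

* **curviness** — the turning angle between the incoming and outgoing
  segments at each interior fix, in [0°, 180°] with 0° = collinear. Any
  monotone use of the feature is invariant to choosing the supplementary
  convention.
* **sample entropy** — SampEn(m = 2, r = 0.2·sd) with Chebyshev
  distance; a constant series yields 0, and when no (m+1)-template
  matches the value is capped at ln(B) + ln(10) to stay finite.
* **autocorrelation first peak** — biased normalized autocorrelation
  over lags 1..n/2; the first lag strictly above its predecessor and at
  least its successor; (0, 0) when the series is constant or no peak
  exists.
* **speed/heading series** — the GNSS channels, with positional
  fallbacks (distance/Δt, initial bearing) where the channel is absent.
* **delta_distance** — unfiltered minus filtered baseline distance; in
  practice non-negative since filtering removes path-inflating noise.

Statistics of series too short to compute are set to 0 with a logged
warning rather than failing the whole vector.

## Screening, selection, collinearity, classification

Screening computes the point-biserial correlation and two-sample KS
statistic per feature against the binary target, flagging p < 0.05.
Feature selection repeats cross-validated recursive feature elimination
(L2-logistic base estimator, subset size maximizing mean CV accuracy)
five times over different participant-grouped 10-fold splits; features
present in ≥ 3 of the 5 subsets form the consensus. Collinearity is then
removed iteratively: while any VIF exceeds 2.5, the worst feature is
merged with its most-correlated partner into the sum of their z-scores
(named "a+b") — raw scales differ by orders of magnitude, so summing
standardized constituents is the only sensible "linear combination".

Classification evaluates logistic regression, RBF-SVM and random forest
under stratified 5-fold CV. Standardization is fitted per training fold
to avoid test-set leakage (a single global normalization pass is
available behind `global_standardization=True` for fidelity
comparisons). Metrics (sensitivity, specificity, F1, accuracy, AUC) are
computed once on pooled out-of-fold predictions, class metrics at
threshold 0.5; the SVM contributes margin scores to the AUC, which ranks
identically to calibrated probabilities. Reported logistic odds ratios
are exp of full-data-refit coefficients on standardized features (per
one SD of input).

## Reference logistic models

The published equations are shipped verbatim: error-based
z₁ = −0.22 + 0.26·X1 + 0.52·X2 + 0.51·X3 − 0.18·X4 + 0.26·X5 and
user-based z₂ = 0.90 + 1.03·X1 + 0.81·X2 − 2.65·X3 + 1.54·X4, with
their feature bindings (e.g. X4 = deltaheading_mean + deltaheading_iqr
as a sum of standardized constituents). The standardization statistics
behind those coefficients were never published, so the packaged defaults
are fitted on a fixed simulated cohort (seed 20240408, 8 participants ×
8 tests, `scripts/build_reference_stats.py`); callers can supply their
own (mean, sd) pairs. Consequently absolute probabilities from raw
features are approximate and can be far off for data unlike the
simulator's; only the closed-form value at standardized-zero input
(user-based: 1/(1+e^{−0.90}) = 0.7109) and the per-input monotonicity
implied by the coefficient signs are exact properties.

## Simulator

The simulator is the package's study-condition generator, not a
physically detailed GNSS model. True paths are 1 Hz polylines: straight
walking at 1.3 m/s mean speed with 0.1 m/s per-second jitter; stop-and-go
alternates 30–60 s walking with 15–30 s standing; back-and-forth uses
20 m legs with instantaneous U-turns; circles use radii 15/10/6/3 m for
circles0..3 (the decreasing-radius family; exact radii are our choice
and configurable). The reference distance is the true polyline arc
length, standing in for the trundle wheel.

Observation noise is first-order Gauss–Markov per planar axis (defaults
sd 3 m, correlation time 20 s): correlated noise is the minimal model
under which filtering helps rather than being trivial. Because sharp
direction changes are a recognized cause of degraded smartphone
positioning, the local noise scale grows with the true turning rate
(`turn_noise_gain`, default 1.5 per 90°/s; the reported accuracy radius
grows with it too). This term is what makes tight circles harder to
measure than straight walks in simulation — without it a
shape-independent noise model would inflate all paths about equally,
contrary to what is observed on real recordings. Cadence (1.8 steps/m),
acceleration magnitudes (≈ 1.2 m/s² walking, ≈ 0.05 standing) and the
artifact channels (≈ 1 % each of teleport outliers at 60–150 m, stale
repeated fixes, and missing-altitude fixes carrying extra 10–20 m
position error) are plumbing chosen to exercise filters R1/R3/R4/R5/R6.

**What simulator-based validation shows** — that the pipeline's
machinery behaves as designed: filtering strictly reduces baseline
error when artifacts are present, the path-shape error ordering
(circles3 > circles0 > regular) emerges, turning-rate features separate
conventional from unconventional walks, and the classifiers recover
that separation. **What it does not show** — absolute error magnitudes
on real phone data (multipath, urban canyons, antenna handling are not
modelled; simulated error levels depend directly on the chosen noise
scale), realistic heading/step-counter failure modes, or the real-data
performance of the published reference coefficients.

## Problem sizes and determinism

Validation cohorts are desk-scale by design: 40 traces of 300 s for the
filtering/shape analyses and 10 participants × 10 tests for the
classifier, sizes at which every qualitative effect above is already
stable across seeds. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical
cohorts and fully reproducible model metrics.
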