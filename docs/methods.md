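# Methods

## The model

A landing approach is described by the perpendicular distance to the
platform y(t) > 0, sampled uniformly (default 200 Hz). The controlled
quantity is the relative rate of optical expansion r = V/y with
V = −dy/dt; its inverse is the time to contact τ = y/V. Three guidance
laws are implemented in closed form:

* **constant-r**: ẏ = −r·y ⇒ y(t) = y₀·e^(−r t); speed decays in
  proportion to distance, touchdown is approached asymptotically.
* **constant-τ̇**: τ(t) = τ₀ + c·t with c ∈ (−1, 0) ⇒
  y(t) = y₀·(1 + c·t/τ₀)^(−1/c); both y and V reach zero at t = τ₀/|c|
  (a soft touchdown), and along the track ln r is exactly affine in ln y
  with slope c.
* **hybrid**: K constant-r bouts whose set points rₖ\* step upward along
  ln rₖ\* = c·ln yₖ\* + const as distance shrinks, joined by first-order
  relaxations of r (time constant 0.15 s by default). With K = 1 the law
  degenerates to pure constant-r.

Both pure laws are verified against adaptive Runge–Kutta integration of
the governing ODE to ≤ 1e-6 m at every sample.

Traversal times between two distances follow from the same laws:
t_r = ln(y₁/y₂)/r and t_τ̇ = (τ₀/c)·((y₂/y₁)^(−c) − 1). For any
c ∈ (−1, 0) the constant-τ̇ law is strictly faster over the same span
(the inequality (1 − x^a)/a < −ln x for x, a ∈ (0, 1)); this is the basis
of the strategy speed comparison.

## The synthetic dataset

The generator emulates the statistical structure of recorded landing
approaches toward a vertical platform so that every analysis stage can be
validated against exact ground truth. Per treatment cell (3 light levels ×
2 platform patterns × 2 landing types):

* Start distances are uniform in 0.25–0.41 m (the workspace allows at most
  0.41 m in front of the platform); the approach begins with an
  acceleration lead-in during which r ramps linearly up to the first set
  point, because recorded approaches contain an acceleration phase before
  the deceleration that is analyzed.
* Each track's set-point schedule is anchored at a gamma-distributed set
  point (shape 3.59, scale 0.65) evaluated at the reference distance
  0.15 m, multiplied by the cell's log-intercept offset. Brighter light
  raises the intercept (0 / +0.08 / +0.16 in log units, matching the
  ~8–18% speed differences between light conditions); the schedule slope
  is the cell's τ̇ (−0.9 after takeoff, −0.73 from free flight; a single
  overriding c is available for calibration datasets). Anchor draws are
  redrawn until the implied approach speed at 0.15 m lies in the observed
  0.1–0.6 m/s envelope; untruncated gamma-tail draws would imply ~1 m/s
  approaches whose bouts no smoothing filter at this sampling rate could
  resolve.
* Displacement budget: each of the K ∈ {2, 3, 4} bouts covers 13% of the
  total displacement and each transition 14% (single segments and
  two-segment spans then cover ≈13% and ≈40% of the approach, as
  observed); the lead-in absorbs the remainder.
* Set points are anchored at each bout's *time-mean* distance — the
  logarithmic mean of its endpoint distances, since y decays exponentially
  within a bout — which is exactly the quantity the segment summary
  (mean y over the segment) estimates. Anchoring at the arithmetic
  midpoint instead biases the recovered τ̇ by about +0.09.
* Realized set points scatter around the schedule with a per-bout
  log-normal jitter (sd 0.15). Without it, ground-truth records sit
  exactly on per-cell lines and confidence-interval calibration checks
  are vacuous. The jitter is milder than the scatter of real set points,
  which is why simulated transitions increase the set point in ~99% of
  pairs rather than the ~72% seen in the field.
* Tracking noise is white Gaussian position noise (sd 0.2 mm on each
  axis), the simplest model of videographic triangulation error;
  correlated noise is not modeled. x and z carry small smooth drifts so
  ground speed is not purely normal to the platform.

What passing tests on this generator do **not** show: robustness to
correlated or heavy-tailed tracking noise, to aborted or re-targeted
landings, to bout structures that violate the constant-τ̇ schedule, or to
the much wider set-point scatter of real bees.

## Kinematics

Positions are smoothed with a centered Savitzky–Golay filter and V, A are
the analytic derivatives of the local polynomial. Defaults: window 15
samples (0.075 s at 200 Hz), polynomial order 3.

* The window must stay shorter than the bouts it must preserve: typical
  bouts last ~0.1 s (0.035 m at ~0.35 m/s). A 21-sample (0.105 s) window
  smears bout edges into the transitions and costs several percent of
  bout recovery; below 15 samples noise fragments the slow approaches.
* Odd polynomial order matters: an order-2 fit leaves a (r·Δt)²-scale
  multiplicative bias on the first derivative of exponential-like signals
  (~0.1% at r = 2), which order 3 removes (≤ 1e-6) while leaving the
  second derivative unchanged.
* A carries the curvature bias of the local fit, growing as r rises
  toward touchdown; V and A are accurate to 0.2% above ~0.02 m and
  ~0.08 m respectively.

Samples within half a window of either track end, or with y at or below
the touchdown threshold y_td = 0.005 m (the touchdown distance is not an
observable; 5 mm is roughly a body length), are masked. τ is defined only
where V > 1 mm/s. Deceleration phases are maximal runs of valid samples
with V > 1 mm/s and dV/dt < 0; interruptions shorter than 0.05 s (the
scale of noise-induced acceleration flickers at the default noise) are
bridged. The maneuver start is the first sample of the last contiguous
approach run ending at touchdown.

## Constant-r segment detection

Within each deceleration phase, every window [i, j] is a candidate if it
covers ≥ 0.01 m (about a third of the typical bout displacement, so real
bouts pass and single-sample flukes do not) and lasts ≥ 0.05 s. A
candidate is *admissible* at sensitivity f when

1. sd(r)/mean(r) ≤ f·tol_r/√3, with tol_r = 0.10 — i.e. r stays within a
   band of half-width f·10% of its mean, enforced through the standard
   deviation. The sd form is deliberate: the raw range of n noisy samples
   grows like √(2 ln n)·σ, so a range criterion splits long genuine bouts
   at any noise level, inverting the intended behavior that larger f
   admits *wider* segments.
2. |least-squares slope of r on t| / mean(r) ≤ f·tol_slope, with
   tol_slope = 0.2 s⁻¹ — a drift guard: a slowly drifting r (as under a
   constant-τ̇ law, where d ln r/dt = |c|·r) can keep its spread small on
   short windows while never being constant.

Selection is greedy longest-first (ties: smaller spread, then earlier
start), with two deterministic refinements: a window colliding with an
earlier selection is trimmed to the free run at either end and kept if
still admissible, and adjacent selections whose pooled window is itself
admissible are merged. An exact maximum-coverage dynamic program over the
same admissible set serves as the test oracle; greedy coverage is ~98–99%
of the optimum in aggregate, with rare noise-kink splits dipping to ~0.83
on single tracks (no longest-first rule avoids those).

Because greedy selection alone does not guarantee that coverage grows
with f even though the admissible set does, the f-sweep carries a lower-f
selection forward whenever it covers more than the fresh one (it remains
admissible at the higher f); per-track covered samples are then
non-decreasing in f by construction. Note that the *number* of segments
is not monotone in f: adjacent windows merge into fewer, wider segments
as f grows.

Each final segment is summarized by its mean y, V, A and r (the set-point
estimate r\*; a through-origin slope of V on y is available behind
`r_star_estimator="slope"`) and its displacement Δy₁. Consecutive
segments are paired, recording the combined displacement Δy₂, the
set-point change Δr\*, and whether the transition contains near-zero
approach velocity (V < 0.05 m/s).

Recovery against ground truth is scored on bouts displacing ≥ 0.02 m,
after clipping each bout to the samples where detection is defined at all
(inside a deceleration phase and the validity mask); a bout is matched
when one detected segment overlaps ≥ 50% of the clipped bout. Under the
default conditions ~92% of bouts are matched and essentially all matched
set points are within 10% of truth. The residual misses are bouts whose
duration falls below the smoothing resolution (fast, late bouts) and
near-touchdown stretches where the noise on r = V/y diverges as y → 0.

## Statistics

* **τ̇ estimation**: ln r\* regressed on ln y\* by REML linear
  mixed-effects (statsmodels MixedLM), random intercept per track (the
  dominant dependence; bee identity is unavailable), treatment factors as
  fixed effects, and ln y\*-slope interactions with pattern and landing
  type. Interaction screening (optional) drops terms with likelihood-ratio
  p > 0.05 from ML fits before the final REML fit. When the mixed fit is
  singular — noise-free data or one record per track — the fixed effects
  fall back to OLS with zero group variance. Natural logarithms
  throughout; no multiple-testing correction across contrasts.
* **Marginal means**: the linear predictor at ln y_ref (default 0.15 m,
  the average segment distance) is averaged with equal weights over
  non-focal factor levels and back-transformed, r\* = exp(·), without
  smearing correction; V\* = y_ref·r\*. Standard errors by the delta
  method from the fixed-effects covariance.
* **Gamma fit**: pooled set points are fitted by maximum likelihood with
  the location fixed at zero (scipy's analytic fixed-location path);
  confidence intervals are seeded nonparametric bootstrap percentiles
  (default 1000 resamples).
* **Transitions**: fraction of pairs with Δr\* > 0, mean/sd of the
  increases, displacement fractions Δy₁/Δy and Δy₂/Δy normalized by the
  maneuver displacement, and the near-zero-V fraction. An empty pair list
  yields n = 0 statistics, not an error.
* **Speed ratios**: over each pair's span, U_H = Δy₂/elapsed time is
  compared with Δy₂/t_r (constant-r at the first segment's set point) and
  Δy₂/t_τ̇ (constant-τ̇ at the dataset-average c, with τ₀ = 1/r\* of the
  first segment, i.e. speed-matched at the span start). The τ̇ reference
  is exactly self-consistent only when the first segment is short enough
  that its mean r equals r at the span start; identity tests construct it
  so.
* **Average-per-treatment analysis**: per-track bin means of V and r
  (0.01 m bins) within deceleration phases, averaged across tracks (≥ 5
  tracks per reported bin); the window set point is the track-weighted
  mean of r over 0.04–0.11 m, a fixed window, with its SE across tracks.
  Treatment contrasts come from OLS on per-track window means — one value
  per track, so a random intercept would be unidentifiable.

## Problem sizes and seeds

The test suite and the acceptance script regenerate all data; nothing is
stored. Default analysis datasets use 25 tracks per cell (300 tracks);
recovery checks use ~200 tracks; τ̇ recovery uses 504 tracks with 25
replicate ground-truth fits; gamma calibration uses 200 replicates of
n = 500 with 200 bootstrap resamples; the treatment-ordering check uses
60 tracks per cell (720 tracks), because the ~8% light steps are small
against the wide between-track set-point scatter. All randomness flows
from explicit integer seeds through numpy Generators.

## Known limitations

* The detector's admissibility rule and the maneuver-start/touchdown
  definitions are this package's concrete choices; other segmentations
  (e.g. penalized changepoint models) are out of scope.
* Set-point recovery degrades near touchdown (noise on r diverges) and
  for bouts shorter than the smoothing window; the per-track method
  shares this limitation with any windowed estimator.
* The pooled set-point distribution of the synthetic dataset is more
  dispersed than a field distribution would be, because the schedule is
  sampled all the way down to 5 mm where set points are large; gamma
  parameters reported on synthetic data therefore characterize the
  generator, not bees.
* Mixed-model τ̇ estimates from detected segments carry a small
  structural bias (|bias| ≈ 0.03–0.05) from segment-boundary truncation;
  ground-truth-record fits are unbiased.
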