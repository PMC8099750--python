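# beeland — per-track analysis of landing deceleration under optic-flow guidance

When a flying insect lands, the only cue it can read directly from optic
flow is the **relative rate of expansion** of the approaching surface,
r = V/y — approach speed over distance, the inverse of the time to contact
τ = y/V. Classic analyses that average many approaches conclude that bees
hold r at a single set point while decelerating (speed falls linearly with
distance). Track-by-track analysis tells a richer story: individual
approaches consist of several short **constant-r bouts**, and from bout to
bout the set point r\* steps *upward* as distance shrinks, following

&nbsp;&nbsp;&nbsp;&nbsp; ln r\* = τ̇ · ln y\* + const,&nbsp;&nbsp;τ̇ ∈ (−1, 0),

i.e. a constant time-to-contact-rate schedule — a discrete approximation of
the continuous constant-τ̇ braking law of landing birds. This package
implements that per-track analysis as a tested pipeline, together with the
synthetic trajectory generator needed to validate every stage against known
ground truth:

* `beeland.flight_simulator` — closed-form generators for the three
  guidance laws (constant-r, constant-τ̇, hybrid bouts-plus-transitions),
  tracking-noise model, and a full-factorial dataset generator
  (3 light levels × 2 platform patterns × 2 landing types) with
  gamma-distributed set-point anchors and exact bout annotations.
* `beeland.kinematics` — Savitzky–Golay smoothing and differentiation;
  V, A, r, τ per sample; deceleration-phase isolation.
* `beeland.segment_detection` — the core algorithm: admissible-window
  enumeration with a sensitivity factor *f*, greedy longest-first selection
  with trim-to-fit and admissible merging, an exact dynamic-programming
  oracle, the *f*-sweep, and consecutive-segment pairing.
* `beeland.setpoint_dynamics` — linear mixed-effects model of ln r\* on
  ln y\* (random intercept per track, treatment fixed effects and slope
  interactions; the slope is the τ̇ estimate), marginal means at
  y\* = 0.15 m, gamma fit of the pooled set points, transition statistics.
* `beeland.strategy_comparison` — closed-form traversal times of the pure
  laws and the speed ratios U_H/U_r and U_H/U_τ̇ over two-segment spans.
* `beeland.average_analysis` — the literature-style average-per-treatment
  method (bin-averaged V(y), window-mean set point in 0.04–0.11 m) for
  contrast.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each stage reads and writes CSVs under `results/`:

```sh
python analysis/01_simulate_dataset.py --seed 0 --n-per-cell 25
python analysis/02_compute_kinematics.py
python analysis/03_detect_segments.py
python analysis/04_setpoint_model.py
python analysis/05_compare_strategies.py
python analysis/06_average_analysis.py
```

`04_setpoint_model.py` prints, for the default seed-0 dataset
(300 tracks, 1063 detected segments):

```
gamma fit of 1063 set points: shape a = 1.09 [1.04-1.14], scale b = 4.06 [3.68-4.50], median r* = 3.17 /s

log-log mixed model (mixedlm), n = 1063 segments in 300 tracks
pooled tau-dot estimate (reference cell slope): -0.785 +/- 0.006
  tau-dot, takeoff: -0.927
  tau-dot, free_flight: -0.785

marginal set points at y* = 0.15 m:
 light   r_star  r_star_se   V_star
  high 2.259662   0.090390 0.338949
   low 2.139227   0.085309 0.320884
medium 2.139546   0.085483 0.320932
```

Read: set points scatter widely but follow ln r\* = τ̇ ln y\* + const
with τ̇ ≈ −0.79 for free-flight landings and ≈ −0.93 for landings
directly after takeoff (steeper braking), and the set point at 0.15 m is
highest in the brightest condition — the treatment structure the generator
embeds, recovered end-to-end from noisy trajectories (at 25 tracks/cell
the small low-vs-medium step is at the resolution limit; the acceptance
test resolves the full ordering at 60 tracks/cell).
`03_detect_segments.py` reports 91.6% of generated bouts matched, with
100% of matched set points within 10% of ground truth, and an *f*-sweep
whose covered fraction grows from 0.15 (f = 0.25) to 0.81 (f = 2.5).
`05_compare_strategies.py` reports, over 763 two-segment spans,
U_H/U_r = 1.61 ± 0.67 and U_H/U_τ̇ = 0.93 ± 0.10: the stepped strategy is
much faster than holding the first set point but slightly slower than
continuous constant-τ̇ braking.

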