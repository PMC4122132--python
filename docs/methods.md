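# Methods

## Signal model

A recording is a time series of the three linear channels (D_x, D_y, D_z)
of a 6-axis force sensor at a nominal 100 Hz with 3 mN resolution; the
insertion axis is aligned with D_z by the experimental setup. All metrics
operate on the scalar force norm F(t) = ‖(fx, fy, fz)‖₂, which is invariant
under rotations of the sensor frame and reduces to |fz| in the aligned
case. Torque channels are read and stored but never enter a metric.
Irregular sampling is tolerated: integration and differentiation use actual
timestamps rather than assuming a uniform grid. The insertion window
(start/end of array advancement, determined externally, e.g. by synchronized
video) is an explicit input to `trim_to_insertion`; by default the full
trace is analyzed.

## Metrics and numerical choices

* **Peak force** — the trace maximum.
* **Momentum (impulse)** I = ∫ F dt — trapezoidal rule on the actual
  timestamps (second order; exact for piecewise-linear signals, which is
  what the closed-form tests use). A left-Riemann option exists for
  sensitivity analysis.
* **Over-threshold occurrences** Th — number of maximal contiguous
  excursions with F strictly above the 0.1 N threshold; an excursion
  already in progress at the first sample counts. Event counting (rather
  than counting samples above threshold) keeps the statistic on the scale
  of discrete loading episodes; sample counting at 100 Hz would be three
  orders of magnitude larger and dominated by excursion duration. A
  `samples` mode is available.
* **Sudden rises** G — the trace is decimated to a grid with spacing
  h = 0.1 s (nearest native sample to each grid time; at 100 Hz this is
  every 10th sample) and G counts consecutive grid pairs with
  F(t)/F(t−h) ≥ 2. The ratio bound 2 (a doubling) is the default; 1.5 (a
  literal "+50%") is available via `rise_ratio`. Ratios whose denominator
  is below the 3 mN sensor resolution (`denom_floor`) are skipped: below
  resolution the denominator is noise and the count would diverge at quiet
  baselines. A zero denominator never counts.
* **Jerk RMS** — J = dF/dt by first differences at native sampling
  (`native_diff`, default; n = trace length − 1 derivative samples), RMS
  over those samples. A `lagged_diff` scheme differentiating over the
  0.1 s grid is provided because the differentiation step is a genuine
  modelling choice: at native sampling the RMS is dominated by
  sensor/tremor noise amplified by the 10 ms step, while the lagged scheme
  emphasizes gesture-scale changes.

Degenerate inputs raise validation errors rather than returning NaN: peak
needs ≥1 sample, momentum ≥2, jerk ≥3, and the sudden-rise scan requires
the trace to outlast one grid step.

## Synthetic archetypes

No insertion-force recordings are publicly deposited, so the cohort stages
are exercised on a seeded generator of three force-profile archetypes,
each a deterministic function of parameters + seed:

* **motorized** — a contact pedestal (`baseline`, 0.015 N) for the first
  half, then a smoothstep rise to `base_peak` at the final sample
  (monotone, peak-free). Duration 21.25 s = 17 mm active array length at
  the 0.8 mm/s actuator speed.
* **forceps** — a shallow ramp plus `n_transients` = 12 Gaussian bumps at
  random times whose amplitudes grow with their position in the insertion;
  the noise-free profile is rescaled so its maximum equals `base_peak`
  (0.26 N), which therefore lands late. Duration 40 s.
* **hifocus_tool** (commercial insertion tool) — the motorized backbone
  (base_peak 0.33 N, duration 30 s) decorated with 5 small transients
  (18% of base_peak). With no transients and no noise it coincides exactly
  with the motorized backbone.

All profiles get additive Gaussian tremor/sensor noise, are quantized to
the 3 mN resolution and clipped at zero, so every sample is a non-negative
integer multiple of the quantization step. Noise SD is technique-specific —
forceps 4 mN, commercial tool 3 mN (one hand free to stabilize), motorized
1.5 mN (held by a flexible arm, sensor noise only) — because hand tremor,
not the backbone shape, is what separates the techniques' jerk RMS at
100 Hz. This tremor model is the package's design choice; it reproduces the
reported qualitative ordering (motorized smoothest) and the excursion/
sudden-rise orderings forceps > commercial tool > motorized.

`simulate_cohort` draws per-recording child seeds and multiplicative
jitter on `base_peak` and duration (relative SD `param_jitter`, default
0.15 — the scale of the between-specimen spread reported for peak force)
from a single master-seeded generator, assigns insertion orders (balanced
1,2,3 cycling by default), and can inject an order effect as a per-order
`base_peak` multiplier.

What the generator does **not** emulate: insertion-depth/angle kinematics,
scala-tympani friction mechanics, basilar-membrane rupture, operator
learning, or the true per-technique durations (not reported; the defaults
are plausible orders of magnitude). Passing tests therefore show the
pipeline is correct and calibrated on signals with the documented
qualitative structure — not that it reproduces cadaver statistics.

## Cohort statistics

Summaries are mean ± sample SD (n−1); an n = 1 group reports SD as NaN,
never 0. Technique contrasts are unpaired one-way ANOVAs of each technique
against the forceps reference, two groups at a time (F = t²), with no
multiple-testing correction — matching how the original comparison was
reported, although the underlying design is repeated-measures; a paired
analysis is out of scope. Zero-variance cases are pinned down: identical
groups give P = 1, perfectly separated constant groups give P = 0
(flagged as below machine floor in the report).

**Insertion-order screen.** Repeat insertions can widen the cochlea and
systematically lower later forces. The screen centres peak force within
technique (removing the technique effect), runs a single omnibus one-way
ANOVA across insertion orders, and — if significant at α — excludes the
most deviant order cohort-wide. A single pooled decision test keeps the
null exclusion rate at the nominal α (a per-technique, per-order battery
would inflate it several-fold); per-technique order-vs-rest contrasts are
still reported for inspection. Monte-Carlo checks in the test suite
confirm both calibrations: two-group ANOVA type-I error 0.03–0.07 at
α = 0.05 over 2000 null cohorts, and screen null exclusion near α over
400 cohorts.

## Problem sizes

The test suite and acceptance script use the study's group sizes (10/8/8)
for pipeline runs; 200 seeds per technique for the archetype-ordering
checks; 2000 (tests) / 400 (acceptance script) replicates for the ANOVA
type-I calibration; and 400 / 200 cohorts for the screen null rate. These
sizes put Monte-Carlo error well inside the asserted bands while keeping a
full run in tens of seconds.

## Known limitations

* Event/threshold semantics (excursions, ratio bound, denominator floor)
  are documented choices where the metric definitions leave room; the
  configuration object exposes each of them for sensitivity analysis.
* The ANOVA treats insertions as independent although repeated insertions
  share specimens; with strong between-specimen correlation the reported P
  values are approximate.
* The archetype generator is a test harness with qualitative fidelity;
  its metric means should not be read as predictions for cadaver data.
* Force-vs-insertion-angle representations and torque-based metrics are
  out of scope.
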