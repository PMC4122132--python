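# insertmetrics

Quality metrics for cochlear implant electrode array **insertion forces**.

During cochlear implantation a flexible electrode array is advanced into the
scala tympani; the friction/contact forces of that gesture correlate with
intracochlear trauma and loss of residual hearing. Given a force-vs-time
recording of one insertion — the Euclidean norm F(t) of the three linear
channels of a 6-axis force sensor, sampled at ~100 Hz with 3 mN resolution —
this package computes five quality metrics:

| metric | definition | unit | what it captures |
|---|---|---|---|
| peak force | max F(t) | N | worst instantaneous load |
| momentum (impulse) | I = ∫ F(t) dt | N·s | total mechanical exposure |
| over-threshold Th | excursions of F above 0.1 N | count | potentially damaging episodes |
| sudden rises G | steps with F(t)/F(t−h) ≥ 2 on an h = 0.1 s grid | count | "fits and starts" discontinuities |
| jerk RMS | √((1/n) Σ (dF/dt)²) | N·s⁻¹ | smoothness of the gesture |

Around the metrics it provides: delimited-text I/O for force recordings, a
seeded generator of the three technique-specific force-profile archetypes
(manual forceps, commercial insertion tool, motorized tool), an
insertion-order screen that discards repeat insertions showing a systematic
force drop, and per-technique summaries with one-way ANOVA contrasts against
the manual-forceps reference. It is aimed at labs benchmarking insertion
tools or techniques on temporal-bone or phantom models.

## Worked example

```python
from insertmetrics import default_params, simulate, force_norm, compute_metric_set

rec = simulate(default_params("forceps", seed=1))      # one synthetic insertion
ms = compute_metric_set(force_norm(rec))
print(ms)
```

```
MetricSet(peak=0.261, momentum_I=0.8115450000000002, over_threshold_Th=8,
          sudden_rise_G=51, jerk_rms=0.5799202531383124, duration=40.0)
```

The simulated forceps insertion peaks at 0.261 N, accumulates 0.81 N·s of
impulse over its 40 s, exceeds the 0.1 N threshold during 8 distinct
episodes, and shows 51 sudden force doublings — the signature of repeated
grasp–release advancement. The same call for `"motorized"` (seed 1) gives
`peak=0.264, momentum_I=1.62, over_threshold_Th=4, sudden_rise_G=0,
jerk_rms=0.245`: a similar peak but a single smooth rise with no
discontinuities and less than half the jerk.

## Analysis pipeline

The `analysis/` scripts run the full study on a synthetic cohort at the
group sizes of the original experiment (10 forceps / 8 commercial tool / 8
motorized):

```bash
python analysis/01_simulate_cohort.py     # recordings -> scratch/, manifest -> results/
python analysis/02_compute_metrics.py     # per-insertion metrics -> results/metrics.csv
python analysis/03_screen_and_compare.py  # order screen, summary + ANOVA -> results/
python analysis/04_calibration.py         # Monte-Carlo type-I calibration -> results/
```

The same pipeline is available as a CLI
(`insertmetrics simulate|compute|compare|run`, see `--help`) for real
recordings: CSV/TSV files with columns `time_s, fx_n, fy_n, fz_n`
(or a precomputed `time_s, f_norm_n`), listed in a manifest.

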