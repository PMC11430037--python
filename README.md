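# dysglyc

Glycemic-index analysis for irregularly sampled ICU blood-glucose time
series, aimed at the study design where a cohort splits into patients with
and without a mid-stay clinical event — the motivating case is delayed
cerebral ischemia (DCI) after aneurysmal subarachnoid hemorrhage — and each
event patient's monitoring is divided into a pre-onset and a post-onset
window. It is written for intensivists and biostatisticians who have
per-patient glucose measurements with exact timestamps (e.g. from blood-gas
analyzers) and want sampling-robust summaries, event-aligned dysglycemia
curves, and the accompanying statistics.

## Indices

For a patient's measurements (t₁, g₁), …, (tₙ, gₙ) (hours, mg/dL) inside an
analysis window:

- **MBG** — mean blood glucose: (1/n) Σ gᵢ.
- **TWAG** — time-weighted average glucose: the trapezoidal area under the
  piecewise-linear curve through the measurements divided by the hours
  analyzed, ∫g(t)dt / (tₙ − t₁); robust to uneven sampling.
- **CV** — glycemic coefficient of variation: 100 · SD(g) / MBG (percent,
  sample SD).
- **AACTD** — average absolute change by time difference:
  mean over consecutive pairs of |gᵢ₊₁ − gᵢ| / (tᵢ₊₁ − tᵢ), in mg/dL/h.
- **TUDR** — time-unified dysglycemic rate: the monitoring time is cut into
  fixed periods (1/3/6/12 h; the length is calibrated so that the median
  per-patient period coverage reaches 95%, taking the shortest qualifying
  length); a period is dysglycemic if any value leaves the target corridor
  (< 70 mg/dL or above a 140/160/180 mg/dL cutoff); the individual TUDR is
  the ratio of dysglycemic to evaluated periods. Cumulative TUDR curves
  re-anchor the grid at each patient's own event onset (periods …,−2,−1,
  +1,+2,…) and report, per period, the fraction of measured patients with at
  least one out-of-corridor value.

The statistics module provides Mann–Whitney U / Wilcoxon signed-rank /
(bootstrap-)t group comparisons, Fisher's exact test, a Pearson-correlation
collinearity screen (r ≥ 0.50, transitive closure, lowest univariate-p
member retained) feeding univariate and multivariable logistic regression,
and segmented-OLS interrupted time-series analysis of the event-aligned
curves (level change at onset plus pre/post slopes).

Because clinical cohorts of this kind are rarely shareable, the package
includes a seeded generator (`dysglyc.simulate`) that reproduces the data
structure — 46.4% event incidence, onset uniform on days 3–14, sampling
intervals 4.0 ± 1.6 h (no event) vs 2.8 ± 0.8 h (event), glucose setpoints
125.6 / 130.7 / 149.2 mg/dL with a step at onset, ~18% CV, lag-1
autocorrelated noise — and serves as ground truth for parameter-recovery
tests.

## Worked example

```python
from dysglyc import *

records, traces, truth = generate_cohort(GeneratorConfig(n_patients=151, seed=1))
sel = select_period_length(traces)          # -> 6.0 h
# per-candidate median coverages: 1h 0.264, 3h 0.725, 6h 1.000, 12h 1.000

panels = compute_panels(records, traces, period_length=sel.period_length)
```

On this cohort the median total-window TWAG is 125.1 mg/dL for no-event
patients and 138.0 mg/dL for event patients; within the event group the
pre-onset median is 130.1 and the post-onset median 148.2 mg/dL, and the
paired Wilcoxon test on pre vs post TWAG gives p = 8.7e-13 (n = 68 patients
with both windows evaluable). The median individual TUDR140 rises from
0.32 (no event) to 0.48 pre-onset and 0.79 post-onset.

```python
dci = [r for r in records if r.group == "DCI"]
pts = cumulative_curves(dci, traces, GlycemicCorridor(high=140), 6.0)
frame = curves_to_frame(pts, GlycemicCorridor(high=140))
its = interrupted_time_series(list(zip(frame.period, frame.rate)), series="tudr140")
```

The cumulative TUDR140 jumps from 0.47 in the last pre-onset period to 0.78
in the first post-onset period; the interrupted time series estimates a
level change of +0.31 at onset (p = 4.3e-12) with no significant trend
within either segment — the step injected by the generator, recovered by
the analysis.

The same pipeline runs from the shell on CSV cohorts
(`patients.csv` + `glucose.csv`):

```sh
dysglyc simulate --out-dir cohort --seed 1
dysglyc indices  --in-dir cohort --out panels.csv --period auto
dysglyc tudr     --in-dir cohort --out tudr.csv --cumulative cumulative.csv
dysglyc analyze  --panels panels.csv --cumulative cumulative.csv \
                 --patients cohort/patients.csv --out-dir results
```

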