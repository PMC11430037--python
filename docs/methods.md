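# Methods

## Data model and windowing

All computation is done in decimal hours since ICU admission and mg/dL.
Monitoring is truncated at 336 h (14 days), the window in which the clinical
event of interest (DCI after aneurysmal subarachnoid hemorrhage) is assumed
to occur; later measurements are dropped at read time with a logged count.
For an event patient with onset time T, the *pre* window is [0, T), the
*post* window [T, 336]: a measurement exactly at onset belongs to post
("after onset" semantics). Patients without the event contribute a single
*total* window. A window with fewer than two measurements yields no index
panel for that window (logged), rather than an error — sparse windows are a
normal feature of real cohorts, not a data defect.

## Indices

- **MBG** is the plain arithmetic mean; it is sampling-frequency sensitive,
  which is precisely why the time-aware indices exist alongside it.
- **TWAG** integrates the piecewise-linear interpolant of the measurements
  by the trapezoid rule and divides by the *observed span* (first-to-last
  measurement), not the nominal window length: the curve is undefined
  outside the observed points and is never extrapolated, and windows never
  interpolate across the onset boundary (pre and post curves are
  independent). Trapezoid rather than step (last-observation-carried-forward)
  integration matches the area-under-the-curve definition of the index.
- **CV** uses the sample (n − 1) standard deviation; the convention is
  ambiguous in the clinical literature, so the choice is pinned by tests.
- **AACTD** averages per-pair rates, mean(|Δg| / Δt), rather than total
  variation over total time; the pairwise reading follows directly from
  "average absolute change divided by the inter-measurement time".

## TUDR

Period grids have fixed length L ∈ {1, 3, 6, 12} h. L is calibrated on the
cohort: for each candidate, compute per patient the fraction of grid periods
between their first and last measurement that contain at least one
measurement, take the median across patients, and select the shortest
candidate whose median reaches 95%. The threshold exists to make empty
periods rare before any rate is computed.

Binning convention: periods are half-open [kL, (k+1)L); additionally a final
measurement that lands exactly on the last grid boundary closes the
preceding period instead of opening a new one (include-right last bin, as in
`pandas.cut`). A 30-h trace on a 6-h grid therefore spans exactly five
periods, which is the convention the worked example assumes.

*Individual* TUDR uses admission-anchored grids. Periods with no measurement
are excluded from both numerator and denominator: counting unobserved time
as normoglycemic would bias the rate downward, and the 95%-coverage
calibration makes such periods rare anyway. The alternative (empty periods
count as in-range) is available behind `count_empty_as_normo=True`, exposed
for sensitivity analysis without being endorsed. For event patients the pre
window keeps the admission-anchored grid clipped at onset; a period
straddling onset is evaluated twice, on its pre-onset and post-onset
measurements separately, keeping the two measurement sets disjoint.

*Cumulative* curves anchor the grid at each patient's own onset. Signed
period indices run …,−2,−1,+1,+2,…: period 0 does not exist, −1 ends at
onset and +1 starts at it (half-open at onset, consistent with the window
convention). Per period the denominator is the number of patients with at
least one measurement in it; patients without data in a period are excluded
from that period's denominator, which is why the curves' denominators decay
toward the ±168 h horizon. Within-period TWAG values are computed for
patients with ≥ 2 measurements in the period.

## Statistics

Group contrasts use Mann–Whitney U (unpaired, skewed indices), Wilcoxon
signed-rank (pre vs post within event patients), the two-sample t-test for
baseline continuous covariates, a bootstrap-t (10,000 seeded replicates,
groups recentred to the pooled mean under the null, two-sided exceedance of
|t|) for skewed baseline variables, and Fisher's exact test for 2×2
frequencies. All tests are two-sided; no multiplicity correction is applied
anywhere, matching the exploratory character of the analysis the package
supports. Fully constant data and empty Fisher margins return p = 1 with a
degeneracy flag instead of an error.

The regression cascade screens predictors by Pearson correlation: pairs with
r ≥ 0.50 are merged by transitive closure (so a chain like MBG–TWAG–TUDR140
resolves to a single cluster) and each cluster keeps the member with the
lowest univariate logistic p-value against the outcome, with every decision
logged. Retained predictors get univariate logistic fits (odds ratios per
unit, Wald 95% CIs exp(β ± 1.96·SE) — the CI method is a package choice);
those with p < 0.05 enter one joint multivariable fit. Perfect or
quasi-separation (detected by non-convergence or exploding standard errors)
flags the predictor and keeps it out of the joint model.

The interrupted time series is a segmented OLS — the method label does not
pin a model, so the model form is a package specification:

value ~ β₀ + β₁·k + β₂·step(k > 0) + β₃·(k − k₊)·step(k > 0)

on the signed period index k, where k₊ is the first post period; β₂ is the
level change at onset, β₁ the pre slope, β₁ + β₃ the post slope (tested by a
linear contrast). Each segment needs ≥ 3 points. The series fed to it are
the per-period median of patient-period TWAGs and the cumulative TUDR rate
at each corridor; all four are analyzed and reported.

## Synthetic cohorts

The generator emulates the *structure* of the motivating cohort, with
defaults fixed to its reported conditions: 46.4% event incidence, onset
uniform on [72, 336] h, measurement times as cumulative sums of
truncated-normal intervals (truncation 0.25 h; means/SDs 4.0/1.6 h no-event,
2.8/0.8 h event — truncated-normal rather than lognormal because the
conditions are stated as mean ± SD), glucose = setpoint(t)·(1 + cv·z_t) with
setpoints 125.6 (no event), 130.7 (pre) and 149.2 mg/dL (post), cv = 0.18,
and z_t a stationary standard-normal AR(1) sequence with lag-1 coefficient
0.5. The setpoint switch at onset is a step, not a ramp — the event-aligned
curves of the motivating data show a level shift with no within-segment
trend. Values are floored at 40 mg/dL (an arbitrary but documented
physiological guard). The lag-1 multiplicative noise is a declared stand-in,
not an estimated physiological model: it exists so that consecutive-pair
statistics (AACTD) are finite and tunable.

What the generator does *not* emulate: insulin and nutrition dynamics,
treatment feedback on glucose, measurement clustering around interventions,
missingness correlated with severity, and skewness of the glucose
distribution (the noise is symmetric, so generator recovery tests compare
process means with estimated means; the motivating data report medians,
which for symmetric noise coincide in expectation). Passing recovery tests
therefore shows the pipeline recovers known structure of this form — not
that real cohorts satisfy the model.

## Numerical choices and problem sizes

Round-trip CSV precision is 0.01 h / 0.1 mg/dL. Period-boundary arithmetic
uses a 1e-9 relative guard on floor operations. Recovery suites run at the
default study conditions: 20 cohorts of 400 patients for interval and
setpoint recovery (tolerances 0.2 h and 5 mg/dL), 500 replicates of a
28-period noisy step for the ITS level-change check (within 2σ), and 500
replicates of a 151-patient logistic simulation with a log-OR of 0.02 per
mg/dL TWAG for CI coverage (~95%). Exact-test implementations are checked
against full enumeration oracles at n ≤ 10 and the logistic fit against an
iteratively refined grid search over the hand-written likelihood on a 6-row
fixture.

## Limitations

Admission is time zero; the bleed-to-admission lag is metadata only. The
pipeline assumes exact timestamps and does not model measurement error in
time. Coverage calibration uses the median-of-per-patient-coverage reading
of the 95% rule; the per-candidate medians are always reported so the rule
is auditable. Whether empty periods belonged in the original TUDR
denominator is unknowable from the index definition alone; both conventions
are implemented (see above), with exclusion as the default.
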