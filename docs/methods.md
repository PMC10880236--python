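# Methods

This note documents the models, rules and numerical conventions implemented
in `uprightkit`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Event model

Events are half-open intervals `[start, start + duration)` on a naive local
clock at one-second resolution. The internal vocabulary is `sedentary`,
`standing`, `stepping`, `nonwear`, `other`; source activity codes are mapped
through a *dialect* table (default: 0 → sedentary, 1 → standing,
2 → stepping, 4 → nonwear, anything else → other). `other` is treated as
sedentary when upright events are built: an unrecognised behaviour never
creates or extends an upright event. Steps may only be carried by stepping
events; validation reports (rather than silently repairs) overlaps,
unsorted rows, negative durations, steps on non-stepping rows, and holes in
the stream with no non-wear boundary. Daylight-saving shifts are not
corrected: all day-cutting rules below are deliberately wall-clock rules.

## Waking-day segmentation

A 24 h-worn monitor records sleep as long sedentary events, so waking time
is cut heuristically:

* everything after a participant's first non-wear bout is dropped
  (participants are assumed not to reattach the device);
* for each calendar date after the first recorded (partial) date, the
  window opens at the **start** of the first standing/stepping event of
  ≥ 10 s beginning at or after 03:00 — an approximate population mid-sleep
  anchor — and closes at the end of the last event that does **not** cross
  the following midnight. The crossing event itself (typically the
  overnight sedentary bout) is dropped, not clipped; users comparing
  against conventions that clip it at midnight should expect slightly
  longer wear times there.

Open-design choices, fixed as follows: "at or after 03:00" is inclusive of
the anchor; an upright event that spans 03:00 but starts earlier does not
open the day (the rule keys on event start); if a recording simply ends
with no midnight-crossing event, the window closes at the end of the last
recorded event and the 10-hour validity gate below guards against truncated
tails.

Validity and inclusion gates (all configurable for sensitivity runs):
≥ 10 h waking wear **and** more than 3 upright events of ≥ 10 s per day;
≥ 6 valid days per participant.

## Upright events and composition

Upright events are maximal runs of consecutive standing/stepping rows;
sedentary events are the complementary runs. Runs shorter than the 10 s
classification floor are discarded outright rather than merged into a
neighbour — merging would silently relabel posture time — and the discarded
seconds are tracked so per-day conservation
(`upright + sedentary + discarded = waking wear`) is assertable and tested.

Per-event composition: duration (min), stepping proportion
(100 × stepping/duration), number of stepping events, step count. The
person-level mean pools **all events across valid days** (so heavier days
weigh more); a mean-of-daily-means alternative is available via
`person_mean_composition(..., method="daily")` because day-level summary
metrics are themselves daily means.

## Daily and person-level metrics

Per valid day: upright and stepping event counts, upright/standing/stepping
hours (from the constructed upright events, so standing + stepping =
upright by construction), daily step count over **all** stepping rows,
mean stepping-event duration and steps per event, step-weighted cadence,
and the two burstiness values. Person summaries are unweighted means over
valid days; a metric undefined on some days (e.g. cadence on a stepless
day) is averaged over the days where it is defined, with the defined-day
count recorded — no imputation.

**Step-weighted cadence.** `Σ(steps_i · cadence_i) / Σ steps_i` over
stepping events with ≥ 10 steps, `cadence_i = steps_i / duration_i(min)`.
The ten-step floor exists because very short step flurries cannot carry a
reliable cadence; their steps still count toward the daily total.

**Burstiness.** With `n` same-type events and `r = σ/⟨τ⟩` over the `n−1`
inter-event times (end of one event to start of the next, within the waking
window only — the overnight gap never enters):

    B_n = (√(n+1)·r − √(n−1)) / ((√(n+1) − 2)·r + √(n−1))

Conventions, with rationale:

* σ is the **population** standard deviation of the `n−1` gaps; the
  statistic's bounds hold under either convention, and the population form
  matches the burstiness literature. A `sd_convention="sample"` switch
  exists for comparison with other codebases.
* `n` counts **events**, not intervals, in the correction terms;
  `n_convention="intervals"` is exposed without endorsement.
* `n < 3` or all-zero gaps ⇒ undefined (NaN); that day is simply excluded
  from the person mean of that metric. σ = 0 ⇒ exactly −1.
* In an alternating stream, the inter-event times of one type equal the
  durations of the opposite type, so sedentary-event burstiness reads as
  variability of upright-event durations, and vice versa.

Numerically, B_n is bounded: for `m = n−1` non-negative gaps the
coefficient of variation cannot exceed √(m−1), and at that extreme the
statistic stays strictly below +1 (≈ 0.997 at n = 50). The property suite
sweeps 10⁴ randomized configurations including one-gap-dominant extremes
and checks equality with an independently coded evaluation of the equation
at 10⁻¹² tolerance.

## Association models

"Generalized linear regression" is implemented as a Gaussian family with
identity link — coefficients stay in the outcome's natural units, matching
how such results are reported — with conventional Wald 95 % CIs and
`*/**/***` stars at 0.05/0.01/0.001; no multiple-testing correction is
applied, by design. A `gamma_log` family switch exists for skewed outcomes.
All categorical factors enter simultaneously with treatment coding against
fixed reference levels (male; no qualification; no disability; excellent
health; professional NS-SEC; normal BMI; sitting occupation; never smoker),
plus waking wear time and mean daily step count as continuous adjustments —
the step-count column is dropped when daily steps is the outcome.
Complete-case rows only; a rank-deficient design raises an error naming the
aliased column. Collinearity is screened with the generalized VIF reported
on the per-term scale `GVIF^(1/df)` (the square of the car-style
`GVIF^(1/(2·df))`; identical to the ordinary VIF at 1 df). Sensitivity
refits drop disability levels ("severely hampered", then also "some
extent"); if a factor collapses to one level it is removed from the design
with a warning.

## Synthetic cohorts

The generator's defaults are anchored to published descriptive statistics
for mid-life adults wearing thigh accelerometers and act as calibration
targets for self-consistency tests, not as claims about any real cohort:
≈ 52.9 upright events/day, upright-event duration lognormal with mean
7.26 min (so ≈ 6.4 h/d upright) and CV 1.6, stepping proportion 0.356
(between-person SD 0.06), stepping events ≈ 31 s, cadence normal
(89.5 ± 8.8 between persons, ± 5 within), waking window drawn per day from
wake 06:00–08:00 to sleep onset 22:30–23:30 (≈ 16 h), a partial attachment
day followed by 7 full days, and overnight sedentary events crossing each
midnight so streams are contiguous.

Design choices that matter:

* **The upright-event rate is the primitive.** The per-person sedentary-gap
  mean is derived from the rate, the duration mean and the waking window,
  using the renewal-with-initial-upright expectation
  `count ≈ (W + gap)/(dur + gap)`; deriving the gap (rather than fixing it
  and letting the rate emerge) avoids a ~+6 % Jensen bias from the
  person-level lognormal multipliers and makes the configured rate the
  realised expectation.
* **Dispersion knob.** Sedentary gaps are gamma with shape `k`; large `k`
  gives near-regular gaps (day-level upright burstiness → −1), small `k`
  bursty days. The default `k = 0.3` places mean upright burstiness near
  0.29. The 10 s gap floor and finite-day sampling attenuate realised
  dispersion, which is why `k` is a little below the value obtained by
  inverting the formula at the target.
* **Within-event substructure.** An upright event of duration `D` targets
  `round(p·D)` stepping seconds split over `k ≈ stepping/31 s` stepping
  sub-events alternating with standing, all ≥ 10 s (integer seconds);
  events too short to alternate become a single sub-event typed stepping
  with probability `p`, keeping the expected stepping proportion unbiased.
* **Covariate effects.** Effects are declared on the person-summary scale.
  The event-stream path realises rate, cadence and stepping-proportion
  effects mechanistically; the direct summary path
  (`generate_person_summaries`) realises **all** declared effects as
  metric = baseline + effects + between-person noise + day-averaged noise
  with mutually independent noise terms, so the declared values are the
  true mutually adjusted coefficients. Regression-recovery simulations use
  this path: it isolates the model-fitting stage and makes 100 replicates
  at n = 1000 × 7 days run in seconds. Default injected effects (female
  +4.39 upright events/d and +0.05 upright burstiness; obese −6.38
  events/d and −1232.63 steps/d; physically active occupation +1.05 h/d
  upright) are sized so their Monte-Carlo standard errors at that design
  are well inside a 5 % relative-bias band.
* **Determinism.** One master seed feeds a `SeedSequence` that spawns one
  child stream per participant, so identical config + seed gives
  byte-identical output and participant streams are independent of cohort
  size ordering.

What the generator does **not** emulate: circadian structure beyond the
wake/sleep draws, posture misclassification, autocorrelated day-to-day
behaviour, gait physiology, or the empirical covariance between metrics
(summary-path noise terms are independent). Consequently the generator's
daily step total (~12–13 k) sits above the descriptive step-count anchor —
consistent per-event cadence and proportions cannot simultaneously
reproduce every person-weighted aggregate of the real cohort — and passing
recovery tests demonstrate the *pipeline's* correctness under the stated
model, not the behaviour of any real population.

## Problem sizes used in the shipped checks

Self-consistency of the generator anchors is checked on 120 participants ×
7 days with effects disabled, with tolerances set at ~3 Monte-Carlo
standard errors of the person-level draws (events ± 3.3, upright ± 0.55 h,
cadence ± 2.6 steps/min). Regression recovery uses 100 replicates of 1000
participants on the summary path (≤ 5 % relative bias, per-effect CI
coverage ≥ 90/100 and pooled coverage within [0.92, 0.98] — exact 95 %
coverage at 100 replicates has binomial noise of ±2.2, so a hard 95 cutoff
would reject a correct model too often). Conservation and structural
properties run on small cohorts at several seeds; the burstiness bound
sweep uses 10⁴ draws.

## Known limitations

* The waking-wear heuristic shares the misclassification risks of all
  accelerometer sleep/wake rules; nothing here validates it against sleep
  diaries or polysomnography.
* Proprietary posture classification (raw acceleration → events) is out of
  scope; the package consumes classified event tables only, and the exact
  column layout of vendor exports varies — the dialect layer is the
  adapter point and ships with one documented default.
* Coefficients from the association stage are descriptive, not causal; no
  survey weighting or non-response adjustment is applied.
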