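# Methods

This note documents the models, conventions and design decisions behind
`actipat`: what each stage computes, what the synthetic generator does
and does not emulate, and how the validation experiments are designed.

## Epoch-level preprocessing

Acceleration magnitude is the Euclidean norm of the tri-axial signal
minus one gravity, truncated at zero (ENMO, in milligravities); it is
rotation-invariant and reads 0 mg for a stationary device regardless of
orientation. Samples are averaged over 30-second epochs; an epoch with
no samples is non-wear. Non-wear is additionally detected as any epoch
covered by a window of ≥60 minutes whose magnitude standard deviation
is below 13 mg — the convention of large-scale wrist-accelerometer
protocols — applied to magnitude only so single-channel data are
supported. A recording is valid when total wear time reaches 72 hours;
the rule uses total hours only (no per-time-of-day coverage
requirement).

Two missing-data modes coexist deliberately: magnitude summaries
(means, daily AUC, percentiles, morning-window statistics, L5/M10) use
a series imputed by the same-time-of-day mean across wear days, while
intensity-time, label-based and fragmentation metrics simply exclude
non-wear epochs. Imputation preserves the average diurnal shape that
magnitude summaries integrate over; exclusion avoids inventing state
occupancy that bout and run statistics would misread as real behavior.
If a time-of-day slot has no wear data anywhere, imputation is
impossible and magnitude summaries fall back to the raw series.

## Labels, nights, walking bouts

The analysis consumes per-epoch labels in {sleep, sedentary, light,
MVPA, walking, nonwear}. Externally supplied labels (e.g. from a
trained activity-recognition model) take precedence; otherwise a
fallback labeler thresholds magnitude at 40 and 100 mg and relabels
sustained quiescence (sedentary runs ≥30 min with mean <10 mg) as
sleep. The fallback never emits walking.

Consolidated night-time lying-down windows are computed per
noon-to-noon night so a sleep period is never split by midnight; the
first and last partial days are dropped. The window initializes at the
night's longest sleep run and grows outward in 30-minute blocks while
the adjacent block contains at least 50% sleep epochs, stopping when
neither edge extends. Block length and threshold are configurable; the
published procedures this emulates are iterative consolidation
heuristics whose exact rule is not specified, so the block rule is this
package's concrete, reproducible choice. Movement episodes are the
maximal non-sleep runs inside the window; the get-up time is the window
end.

Ambulatory (walking) bouts are maximal walking runs, optionally merged
across a single non-walking gap: up to 30 s when the merged bout stays
under 10 minutes, up to 1 minute otherwise; merged duration includes
the gap, bouts must start and end on walking epochs, last ≥2 minutes,
and are classed 2–10 / 10–30 / >30 minutes. A gap is never bridged at a
bout boundary.

## Sustained-activity bouts

A bout of an intensity class (sedentary <40 mg, active 40–<100 mg,
MVPA ≥100 mg) is a maximal interval whose boundary epochs satisfy the
class predicate, whose internal non-compliant runs each last at most
`break_tolerance` epochs (default 1), and whose duration reaches the
class minimum (10 min active, 3 min MVPA). These declarative semantics
are authoritative; the production detector implements them by splitting
the recording at "blocker" runs (non-compliant runs longer than the
tolerance, or touching non-wear — non-wear always breaks bouts) and
trimming each segment to its first and last compliant epochs, which
yields the unique maximal set. A brute-force oracle re-derives the same
set by forward-scanning every candidate start; equivalence on random
sequences is part of the validation suite. Sedentary bouts are the
wear-time complement of the union of active and MVPA bouts.

## The metric registry

145 unique metrics carry 147 domain registrations; exactly two metrics
serve two domains ("M10 mean level" in total volume and night; "MVPA
percent of wear time" in total volume and fragmentation). Units are
minutes for times, hours-since-midnight for clock times (averaged
circularly across days), percentages in [0, 100]. The registry file is
the single source of truth for ids, domains, units and scale tags.

* **Total volume (77)** — minutes, percent of wear time and across-day
  SD in ten 40 mg bins (0–40 … 360–400); overall/daily magnitude
  summaries incl. weekday and weekend means and daily AUC; time ≥40 and
  ≥100 mg; bout time, counts, durations and in-bout magnitude; in-state
  magnitude for light/MVPA/walking; walking time; ambulatory-bout
  counts and minutes by class; weekly totals; most-active-day MVPA;
  weekday/weekend MVPA ratio; M10 level.
* **Morning (30)** — mean, SD, 95th centile, AUC, % time ≥40 mg and
  MVPA minutes in windows of 15, 30, 60, 120 and 240 minutes after the
  get-up time, averaged across days; a day is excluded for a window
  that runs past the recording end.
* **Night (15)** — sleep-efficiency mean/SD; sleep-midpoint circular
  mean/SD; L5 and M10 midpoint and level from the across-day average
  24-h profile (per-day L5/M10 is config-gated); nocturnal and diurnal
  sleep-episode duration mean/SD; movement episodes per night mean/SD;
  rest fragmentation (percent non-sleep in the window divided by the
  number of movement episodes; defined as 0 when there are none).
* **Fragmentation (25)** — two binarizations of wear epochs (sedentary
  vs active at 40 mg; MVPA vs non-MVPA at 100 mg); exit hazards as the
  reciprocal mean completed run length; transition probabilities as
  observed exits over total epochs in the state; run-duration mean, SD,
  median and 95th centile per state. The final run of each wear segment
  has no observed exit: it is excluded from hazards and transition
  probabilities (censoring) but included in run-duration statistics.
  On censoring-free geometric runs the hazard and transition
  probability coincide, which the validation suite checks.

Daily statistics are computed per calendar day (local to the
recording's start) and then averaged or SD'd across days; weekends are
ISO Saturday/Sunday.

## Screening, adjustment, profiles, PCA

Each metric is screened by the RA/control geometric-mean ratio with a
Welch (unequal-variance) 95% t-interval on the log-mean difference,
exponentiated. Zeros are offset by half the smallest positive observed
value before the log (config-overridable). A metric is flagged as
potentially differentiating when the ratio deviates from 1 by more than
5% (two-sided) and the CI excludes 1. Clock-time metrics (sleep
midpoint, L5/M10 midpoints) are screened on the linear scale with an
arithmetic-difference CI — a ratio of clock times has no meaning — and
flagged when the CI excludes 0. One-way ANOVA runs on log values for
any categorical factor (group, diagnosis source, diagnosis type,
onset); ANCOVA adjusts the group effect for one covariate at a time
(smoking, alcohol, chronotype, season, working status), with a joint
model available. P-values are exploratory with no multiplicity
adjustment by default; Benjamini–Hochberg reporting is optional and
clearly labeled.

Wake-aligned profiles average per-epoch label indicators (walking
folded into MVPA for the four-class display) across each participant's
days from the get-up time, then across participants within group;
non-wear epochs contribute nothing, and at every bin the class
probabilities of a group sum to 1 over the bins that have contributing
wear time. PCA standardizes each flagged metric to mean 0 / SD 1,
drops metrics with any missing value (recorded) and zero-variance
metrics, and selects the smallest component count whose cumulative
explained variance reaches 70%.

Matching processes cases in seeded random order; each takes its
`ratio` nearest available controls by category distance (infinite
across sexes, otherwise the sum of absolute category-index differences
over age bin, BMI class and ADI quintile), without replacement. The
default caliper is 0 (exact categories) — with a biobank-scale pool
nearly every case matches exactly, and the few that cannot are
reported unmatched rather than matched loosely; relaxed calipers are
opt-in. ADI quintile edges come from the case group and are applied to
both groups.

## The synthetic generator

States follow a semi-Markov process on the 30-s grid. At each entry the
next state `s` (never the current one) is drawn with probability
proportional to `w_s · exp(a_s cos(2π(t − φ_s)/24)) · f_s`, where `w_s`
is a base weight, `a_s` and `φ_s` the entry-modulation amplitude and
peak hour, and `f_s` a person-level log-normal frailty. The sojourn is
geometric on epochs with mean `m_s · exp(b_s cos(2π(t − φ_s)/24))`
evaluated at entry (`b_s < a_s`: occupancy is shaped mainly by entry
rates, run lengths only gently). Defaults produce, for controls, about
8.9 h sleep, 10.9 h sedentary, 2.3 h light, 23 min MVPA and 1 h walking
per day, consolidated nights of ~7 h with ~95% sleep efficiency and
get-up times around 07:10, and weekly MVPA counts large enough that
volume metrics have ~15–25% between-person coefficients of variation.
Magnitudes are label-conditional log-normals — sleep (3 mg, GSD 1.8),
sedentary (9, 1.9), light (60, 1.15), MVPA (180, 1.25), walking (55,
1.20) — chosen so each state's draws respect its intensity class band
(≥99.5% within band, including the person-level magnitude frailty of
GSD e^0.1): the states *are* intensity classes, so label-conditional
magnitude straddling a cutpoint would make labels and thresholds
contradict each other. Non-wear arrives as Poisson episodes (0.15/day,
mean 90 min) during which the recorded signal mimics a stationary
unworn device. Everything is driven by a single `numpy` Generator per
call, so outputs are bitwise-reproducible given a seed; cohorts are
simulated in a lock-step vectorized loop, and a single participant is
the batch of size one.

Disease effects are explicit knobs. `mvpa_time_ratio` multiplies the
per-entry probability of starting an MVPA run — implemented by thinning
accepted MVPA entries (rejected entries redraw among the other states),
because scaling the entry *weight* under self-transition exclusion
realizes only part of the requested reduction (a nominal 0.8 came out
near 0.83); thinning makes the knob exact for ratios ≤1, while ratios
>1 fall back to weight scaling. `mvpa_run_ratio` scales the MVPA mean
sojourn directly. `morning_delay_minutes` ramps MVPA and walking entry
rates linearly from 0 to 1 over the delay window after the reference
wake hour (07:00). `sleep_interrupt_rate_ratio` scales sedentary and
light entry rates inside the nocturnal window (23:00–06:00). The
standard disease condition used in the demo pipeline is 0.8 / 0.85 /
30 min / 1.3.

Demographics follow the study population's marginals — 67.0% female,
74.6% aged ≥60 in 5-year bins, WHO BMI classes, ADI ~ N(−1.48, 2.88²),
smoking, 6-level alcohol, chronotype, season, working status, 74.0%
early onset, 8.7% seropositive — with mild configurable group
imbalances on the post-matching covariates so the covariate-adjustment
stage has real work to do. Control-pool demographics skew younger and
differ in ADI so matching is non-trivial.

What the generator does **not** emulate: raw 100 Hz tri-axial traces,
device calibration or temperature drift, autocorrelated magnitude
within a run, weekday/weekend behavioral differences, medication or
season effects on activity, and any demographic influence on activity
(age and sex do not shift the activity model — only the explicit RA
knobs do). Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under a plausible data-generating process,
not the clinical validity of the metrics on real recordings.

## Validation experiment design

The validation suite (`actipat.validation`, exercised by the test suite
and by `scripts/acceptance.py`) runs at these problem sizes:

* **Bout equivalence** — 1,000 random binary-intensity sequences of up
  to 500 epochs with ~3% non-wear, cycling break tolerances 0–2 and
  minimum durations 3–10 min; the fast detector must match the oracle
  interval-for-interval.
* **Fragmentation identities** — the hazard equals the reciprocal mean
  completed run length exactly on an arbitrary 4,000-epoch sequence
  (checked against an independent run scan), and hazard vs transition
  probability agree within Monte-Carlo error on 10⁵ epochs of
  alternating geometric sojourns.
* **Null calibration** — two effect-free pools of 900 participants are
  simulated and their full 145-metric matrices computed; each of 500
  screens draws an independent random 300-vs-600 group assignment and
  screens one metric, rotating through the registry. Under the null,
  the 95% CI excludes its null value in ~5% of screens and the flagged
  fraction is necessarily smaller. Independent assignments are used
  because screens of many metrics on a *single* simulated cohort are
  strongly correlated through the person-level frailties (about 14
  effective independent screens per cohort), which would make the
  observed fraction far noisier than binomial; the marginal exclusion
  probability is the same quantity either way (verified at 5.4% with
  fresh cohorts at small scale).
* **Effect recovery** — 200 replicates, each a fresh cohort of 300 RA
  (only `mvpa_time_ratio = 0.8` injected) vs 600 controls; per
  replicate the daily MVPA-minutes screen must cover 0.8 and the eight
  MVPA-volume family metrics (threshold time, weekly/most-active-day
  totals, MVPA-bout time/percent/count) are checked for flagging. The
  replicated path simulates cohorts in batch and computes only the
  family metrics, through the production bout-detector core; a unit
  test pins it to the full registry computation.
* **Boundary and structure checks** — the 72-hour wear rule at 71.99 vs
  72.00 h; 2:1 matching on a pool with two exact duplicates per case
  (all matched at distance 0, no reuse, reproducible under the seed);
  profile probability closure to 1e−9; PCA variance fractions summing
  to 1 with the rank-1 two-metric case giving a first fraction of 1.

## Known limitations

The night-window expansion rule, the bout-detector's segment algorithm
and the fallback labeler are reproducible stand-ins for published but
under-specified procedures; absolute metric values on real data will
depend on the upstream labeler. Clock-time SDs use the circular
dispersion, which understates variability for bimodal timing.
Transition probabilities condition on total state epochs, so heavy
censoring (short wear segments) biases them low relative to hazards.
The matching distance treats adjacent categories as equidistant steps;
no caliper on the underlying continuous variables is applied.
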