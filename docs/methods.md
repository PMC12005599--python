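# Methods

This note documents the models, conventions, and numerical choices behind
`ema_context`, and what the bundled synthetic data does and does not
establish about real studies.

## Response scoring

A *prompt* is one scheduled EMA delivery; re-delivery attempts (every 5
minutes, up to the study's maximum) collapse into a single prompt event, so
a prompt counts once in the response rate regardless of how many attempts it
took.  Compliance is graded per prompt: 0 with no answered question, 1 with
all questions answered, otherwise the answered fraction.  Non-question
tasks (shape tests, audio recordings) never enter the denominator — the
data model only carries Likert questions.

Likert scales differ between studies, so every answer is mapped linearly
onto [1, 5]; negatively phrased questions are reflected afterwards
(x → 6 − x, which commutes with the linear map) so that higher always means
more positive.  Time-of-day strata use fixed local-clock boundaries:
morning before 12 PM, afternoon 12 PM through 5 PM inclusive of both
boundary instants (half-open-above would be ambiguous exactly at the
boundary; both 12:00:00 and 17:00:00 are assigned to afternoon),
evening after.  All timestamps are taken on the participant's local clock;
no timezone arithmetic is attempted.  A session whose prompt falls near
midnight is assigned to its scheduled date; `elapsed_day` counts calendar
days since the participant's first prompt.

## Careless responding and habituation

Carelessness is the percentage of a participant's normalized answers within
0.2 (inclusive, with a 1e-9 float guard) of that participant's modal
answer; mode ties break to the lowest tied value so the statistic is
deterministic.  The cohort figure averages per-participant percentages
rather than pooling answers, so large studies do not dominate.  Habituation
splits each participant's *own* collection span at its calendar midpoint
and takes second-half minus first-half differences in carelessness and in
response variance; the cohort change is the mean difference and its
significance a two-sided paired *t* test across participants (the
participant is the natural unit of pairing).  Participants lacking at least
two responses in both halves are excluded and counted.

## Behavior-context markers

All three markers are computed over the half-open window (t − 30 min, t]
ending at the prompt.

* **Activity (watch)** — the sum of acceleration magnitudes in the window
  divided by the window length in minutes.  Per-minute normalization makes
  differently sampled streams comparable; whether the magnitude is
  gravity-subtracted is up to the ingest — values are used as given.
* **Activity (ambient)** — the count of motion-sensor firings in the window.
* **At-home fraction (watch)** — home is the modal night-time (2 AM–9 AM)
  GPS cell on a 10⁻⁴-degree grid (≈11 m, above typical GPS jitter), with
  the cell's centroid as the home coordinate; a fix within 50 m counts as
  at home, and each inter-fix interval takes its starting fix's label.
  When no fix falls in the window the last earlier fix is carried forward
  up to 2 h of staleness; beyond that the feature is the NaN
  "context unavailable" sentinel, dropped pairwise from correlations.
  Distances and bearings use the haversine formula on a 6,371 km sphere.
* **At-home fraction (ambient)** — out-of-home intervals start when an
  external door opens and closes followed by ≥5 minutes without motion
  events, and end at the next motion event.  An unmatched door open is
  treated as the departure, with a warning.
* **Change-point nearness** — exp(−Δ/τ) with Δ the minutes to the nearest
  detected activity change point and τ = 15 min (a bounded, monotone
  nearness usable directly in correlations; 0.0 when no change point
  exists).  Change points come from exact penalized least-squares
  mean-shift segmentation (PELT): minimize within-segment squared error
  plus a per-breakpoint penalty, default 3·log n·var̂ with var̂ estimated
  robustly from the median absolute first difference so the sought shifts
  do not inflate it.  The pruned search is exact for this additive cost;
  a numba-compiled kernel (arithmetic identical to the numpy reference,
  and tested against it) accelerates it.  The pipeline segments the
  activity series in 5-minute bins, a resolution matched to the 5-minute
  location cadence.

The home radius, grid, τ, and the exponential nearness form are this
package's conventions — reasonable defaults, all configurable, not values
taken from any particular deployment.

## Cross-study comparison

DTW uses absolute-difference local cost with symmetric match/insert/delete
steps, no warping window, and unnormalized cumulative cost; inputs are each
participant's raw chronological normalized responses per question category
(not per-day means), and participants with fewer than 5 responses are
excluded as a noise floor.  Within-study distances average over all
unordered same-study participant pairs, between-study over cross-study
pairs, per category; the overall summary averages the three category
summaries, and the headline contrast is the percent increase of the
between- over the within-study mean.  The pipeline caps each pair set at
1,500 randomly sampled pairs per category and side to bound runtime
(the library default enumerates all pairs).

Aggregated series take the mean response across participants at each
response index up to 48.  ARIMA uses order (0,1,1) with no constant —
differencing absorbs the slow trend and the remaining structure is a
first-order moving average — with the Ljung-Box test at 10 lags on
residuals (the first differenced residual dropped).  Degenerate inputs
(zero variance after differencing) return a flagged fit rather than an
exception.  Group trend lines regress each group's aggregated series on the
1-based response index.

## Synthetic-data generator

The generator is first-class: its defaults define the study conditions the
test suite and acceptance run measure against.

* **Cohort** — nine studies, 200 participants, mirroring the spread seen in
  multi-study EMA work: question counts 7–15, two intervention studies
  with lower starting "sharp" levels, one ambient-protocol study, two small
  younger-adult cohorts on a 0–10 raw scale, the rest older adults on 1–5
  or 1–7 scales.  Durations are 14 days (one study 21) with four daily
  prompt blocks — scaled down from multi-month deployments so a full
  20-seed recovery run stays cheap, at the cost of measuring habituation
  over a shorter horizon.
* **Response model** — P(respond) is logistic in: a per-participant
  intercept (SD 0.2 log-odds), a time-of-day offset (evening boost for
  older cohorts, near-flat for younger), the question count, and the three
  true context covariates (at-home fraction +0.8, change-point nearness
  +0.5, standardized activity +0.2 log-odds).  Covariates enter centered at
  reference values matching their realized distributions so the marginal
  response rate stays near the 80% base rate.  The question-count effect is
  calibrated so the measured OLS slope of response rate against question
  count equals −1.9 percentage points per question: the calibration solves
  for β on the exact marginal logistic curve through the design's question
  counts, with the standard logistic-normal attenuation
  σ(x/√(1 + 0.346 v)) for the other random logit terms.
* **Answers** — each participant has a per-category modal value drawn
  around the study-level center and snapped to the study's raw grid; with
  the careless probability (0.35 + 0.012/day, clamped) the mode is emitted,
  otherwise mode + Gaussian noise (SD 1.1 on the normalized scale,
  shrinking linearly to 0.7× across the study), rounded to the raw grid.
  The "sharp" category drifts upward per response, faster in intervention
  (+0.023) than observational (+0.005) studies.  After the first answer,
  each further question drops out with probability 0.02, yielding partial
  sessions.
* **Behavior** — a two-state home/away process: about two log-normal away
  bouts per day (median 45 min — the distributional form is a modeling
  choice, not an observed quantity) displacing the participant 300–2000 m;
  independent at-home activity bouts (~10/day, 30–60 min).  Per-minute
  acceleration is state-dependent (idle 0.3 g, active and away 0.9 g,
  ±2 min around away boundaries 1.8 g); location fixes every 5 minutes
  with 10 m GPS jitter; the ambient variant emits Poisson motion events
  while home and door events at every away boundary with an entry-motion
  burst on return.  Every change of the idle/active/away state is a true
  activity transition.  Keeping away-bout and at-home activity levels equal
  matters: activity, at-home fraction, and transition nearness are mutually
  correlated, and if being away were also the most active state, the
  negative activity–home confound would overwhelm the positive at-home
  effect in the marginal correlations the analysis reports — no parameter
  signs would then be recoverable from observational correlations at these
  effect sizes.
* **Determinism** — one `SeedSequence` per dataset, spawned per study and
  participant, so identical config and seed reproduce logs byte for byte.

What passing recovery tests show: the pipeline's estimators recover the
directions and calibrated magnitudes of effects *under this model* —
logistic response, stationary mobility, drift-plus-shrink answer dynamics.
Real EMA data add missingness mechanisms, device artifacts, schedule
deviations, and context effects that interact; recovery here validates the
estimators, not those assumptions.

## Numerical and degenerate-input conventions

Empty session lists, all-missed cohorts, constant regressors, and
zero-variance features raise `ValueError` rather than returning NaN;
missing context is a NaN sentinel dropped pairwise.  Mode and modal-cell
ties break to the lowest value / south-west cell so results are
order-invariant (centroids sort before averaging for exact invariance).
A within-study DTW mean of zero makes the percent increase undefined and
is reported as NaN (or infinity when the between mean is positive).
Change-point detection on fewer than 4 points returns no breaks with a
warning.

## Known limitations

Watch streams are represented at per-minute resolution (real devices sample
at tens of Hz; per-minute normalization keeps levels comparable but
sub-minute structure is invisible).  The ambient at-home rule cannot see
visitors or multi-occupancy; DTW pair subsampling makes the pipeline
summary stochastic at large cohort sizes (fixed by the run seed); ARIMA is
fit only to aggregated series, never per participant; and no
multiple-testing correction is applied across the correlation family.
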