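# Methods

`adlsense` analyses ambient-sensor streams from the homes of people living
with dementia on two time scales: a **macro** track that models the daily
routine and flags anomalous days, and a **micro** track that detects
hour-scale agitation/irritation/aggression (AIA) episodes by fusing three
sensing groups. Real deployment data of this kind is not publicly
deposited, so the package ships a simulator that generates deployments
with known ground truth; all quantitative statements below are measured
on that simulator by the test suite and `scripts/acceptance.py`.

## Macro track: entropy-rate routine modelling

**Representation.** Events are binned into half-open 10-minute slots, so a
day is a `144 x n` matrix over the `n` active sensors (9 by default).
Per-sensor activity is scaled affinely so the *training* range maps to
[0, 10] (test values clip); the scaling, like every other learned
component, is frozen after training. Days are K-means-clustered (k = 2)
into a low-active category D1 and a high-active category D2, ordered by
total activity, because routines differ between quiet days and busy days.
A second K-means over all training windows (one centroid per sensor by
default, i.e. `n_states = n`) gives a codebook mapping each 10-minute
window to a discrete state; a day becomes a 144-state sequence.

**Model.** For each category a first-order Markov chain is estimated by
count-and-normalise: transition matrix `T[a][b] = #(a->b)/#(a->.)` over
within-day consecutive pairs (sequences never cross midnight) and
occupancy `P_a` as state frequency. Two information measures follow, in
natural log (nats; the base only rescales all quantities together):

* transition entropy `eps = -sum_ab P_ab log P_ab`, and
* entropy rate `xi = -sum_ab P_a P_ab log P_ab`,

with `0 log 0 := 0` and unobserved rows contributing nothing. The
occupancy weighting makes `xi` sensitive to the direction of traffic:
if `P_ab = P_ba` but `P_a != P_b`, `eps` is identical while `xi` is not.
`xi <= eps <= log n_states` always. We use the empirical occupancy, not
the stationary distribution of `T`, because rows with no observed
transitions would leave the latter undefined on short sequences.

**Scoring a day.** A test day is assigned to its nearest day-category
centroid, discretised with the frozen codebook, and scored. The default
score is the day-vs-model **cross entropy rate**: the day's own empirical
`P_a` and `P_ab` weighted against the trained category model's
log-probabilities, `xi_day = -sum_ab P_a(day) P_ab(day) log T_hat[a][b]`,
with `T_hat` additively smoothed (0.01 per cell, renormalised) so
transitions unseen in training incur a large-but-finite penalty. This
score grows whenever the day's sequence distribution deviates from the
learned routine — including days that are internally very regular but
occupy unusual states. The alternative `day_entropy="own"` scores each
day by its own refitted chain's entropy rate; it measures only within-day
irregularity and, by construction, cannot see *which* states a day uses.
In simulation the own-chain variant detects visitor and restless days at
roughly chance (~7%) while the cross variant detects them at 95%+, which
is why cross is the default; both are available.

**Deviation boundaries.** The historical data is split into training and
verification days. With `xi_T` the training chain's entropy rate and
`xi_1..xi_v` the verification-day scores, the band is

    Delta = xi_T ± mu * sigma,   sigma = sqrt( sum_i (xi_i - xi_T)^2 / v ).

`sigma` is a root-mean-square deviation about `xi_T`, so it absorbs both
the spread of verification days and any systematic offset between
per-day scores and the pooled training rate. One `sigma` is estimated
over the whole verification set (each day's deviation measured from its
own category's `xi_T`); each category keeps its own centre. With ~14
verification days a per-category estimate is noisy enough to produce
occasional false-positive bursts. `mu` defaults to 2.0 (~95% coverage of
normal days if deviations are roughly Gaussian) and is configurable.
Flagging is two-sided by default: abnormally *low* scores (away days,
sensor loss) are anomalies too; the one-sided `xi > upper` rule is
available as `mode="one_sided"`.

**Evaluation.** Day flags are aggregated to weeks (a week is labelled
anomalous when >= 2 days are flagged, a choice the data format does not
dictate); the weekly sensitivity `rho` is the fraction of labelled weeks
confirmed by ground truth. Across a cohort, the Pearson correlation
between per-home detected and validated anomaly counts summarises
agreement (both vectors are min-max normalised first; this does not
change the coefficient but matches how the counts are reported).

## Micro track: hierarchical AIA detection

Three sensing groups are scored per day and fused:

* **G1 (physiological).** Twice-daily vitals (systolic/diastolic blood
  pressure, heart rate, body temperature, weight, hydration) are compared
  against clinical thresholds; the expert decision score `D_CS` counts
  vitals strictly outside `[T_L, T_H]` (a value exactly on a threshold is
  in range; the same strict-outside convention is used for box-plot
  bounds and MAD flags). The group's day score is the worst reading's
  `D_CS / |G1|`. Default thresholds (systolic 90–160 mmHg, diastolic
  60–100 mmHg, HR 50–110 bpm, temperature 36.0–37.8 °C, weight 50–110 kg,
  hydration 45–65%) are package defaults, overridable per home.
* **G2 (participant-proximal motion):** chair pressure, bed pressure,
  bedroom-door motion. * **G3 (ambient/multi-occupancy motion):** living
  room, hallway, kitchen. The bathroom-door sensor belongs to neither
  group and does not feed the micro track.

**Label sequences.** Hourly per-sensor aggregates `P_x` (half-open hour
bins, zero-filled) are mapped to two-letter-per-sensor label sets. The
normal range per sensor is learned from historical data with the
skewness-adjusted box-plot: with quartiles Q1/Q3 (linear interpolation),
IQR and medcouple MC,

    MC >= 0: [Q1 - 1.5 e^(-4 MC) IQR, Q3 + 1.5 e^(3 MC) IQR]
    MC <  0: [Q1 - 1.5 e^(-3 MC) IQR, Q3 + 1.5 e^(4 MC) IQR].

Hourly sensor counts are strongly right-skewed, so symmetric Tukey fences
would over-flag the upper tail. The medcouple is computed by the O(n^2)
kernel median over pairs `x_i <= m <= x_j`, `x_i != x_j` — adequate for
the few thousand hourly points involved. (This pair set excludes tied
pairs at the median; implementations that include the tied-pair signum
kernel differ on odd-sized samples, where the median is a data point.)
Labels are globally unique single characters, so concatenating a group's
per-sensor labels in fixed order yields one composite symbol per hour
that decodes unambiguously; a day is a 24-symbol string per group
(`S_G2`, `S_G3`).

**Group HMMs.** Each group has a 2-hidden-state (normal/AIA) discrete
HMM `lambda = {T, B, pi}` over its composite-symbol alphabet. Parameters
are estimated by additively smoothed supervised counting from sequences
with known hidden labels — in this package the simulator's ground truth
plays the role of the original deployment's clinician-curated seed data —
and expert matrices can be installed directly. Inference is standard
forward / forward–backward / Viterbi, in log space so day-length
sequences are stable; Viterbi ties resolve toward "normal" to bias
against false alarms. Baum–Welch refinement is deliberately out of
scope. The group's day score `D_pf` (G2) or `D_mo` (G3) is the mean
posterior P(AIA) over the day's *candidate hours*: hours whose group
total exceeds a median-absolute-deviation threshold learned on training
hours (`|x - med| > k MAD / 0.6745`, k = 3; the 0.6745 factor makes MAD
consistent with a normal standard deviation), falling back to the whole
day when no hour is flagged. MAD seeding keeps a short episode from
being diluted across 24 hours.

**Fusion.** Each group's hard prediction (argmax of its day score) earns
per-class precisions `p_i = TP_i/(TP_i+FP_i)` under stratified k-fold
cross-validation (k = 10, reduced with a warning if the rarer class has
fewer members; precisions are averaged over folds). Normalising over
classes within a group gives reliability weights `Rs_ij = p_ij / sum_i
p_ij`, and the fused decision is `argmax_i sum_j Rs_ij P_j(i)`, ties to
"normal". A missing group's term is omitted. When all precisions are
equal the rule reduces to unweighted score averaging.

A known behaviour of this weighting: each group's reliability column
sums to 1 regardless of how good the group is, and a group that never
predicts AIA (zero AIA precision) contributes *only* to the normal
score. With day-level mean-posterior scores, weakly informative groups
rarely cross 0.5, so the fused argmax label is conservative — the
discriminative power lives in the continuous fused score, which is what
the ROC/AUC evaluation measures.

## The simulator

Each home has nine sensors (2 PIR — hallway, living room; 3 motion —
kitchen, bedroom door, bathroom door; 2 pressure — chair, bed; door
contact; energy meter). Event sensors are inhomogeneous Poisson
processes with piecewise-constant hourly rates encoding a plausible
routine: hallway traffic 8:00–11:00, living-room occupancy 20:00–22:00,
kitchen peaks at meals, bed pressure at night. Rates are tens of events
per hour in occupied rooms — ambient PIR/motion sensors trigger on every
movement — which is what gives the 10-minute windows enough signal for
discretisation to capture routine structure rather than Poisson noise.
The energy meter reports a consumption value every 10 minutes (baseline
plus activity-proportional noise) rather than point events. Days are a
high/low-active mixture (p = 0.5, rate multipliers 1.3/0.7). All
timestamps are naive local time; days break at midnight.

Injected conditions, all labelled in the ground truth:

* **visitor days** — ambient (G3) rates x3 (multi-occupancy);
* **away days** — all non-energy rates x0.02, energy at baseline;
* **dropout** — a named sensor emits nothing over a day range;
* **AIA episodes** — an *additive* extra event rate (+120/h on each G2
  sensor, +30/h ambient echo by default) over the episode hours,
  optionally with physiological excursions that push the listed vitals
  above their clinical thresholds in both of that day's readings.
  Superposition is the physically sensible model: agitated repetitive
  motion is its own process, so identical agitation looks the same at
  any hour and does not vanish over a zero baseline (the chair at
  night), which a multiplier would imply.

What the simulator does **not** emulate: device-specific sampling
artefacts, inter-sensor crosstalk, gradual behavioural drift, seasonal
routine change, multi-home interference, or realistic vital-sign
dynamics (readings are independent truncated normals). Passing tests
therefore show that the algorithms recover the structure the generator
encodes, not that they would reach the same numbers on a real
deployment.

## Reference scenarios and problem sizes

* **Macro scenario** — 60 training + 14 verification + 60 test days; 10
  anomalous days injected into the test stretch (4 away, 3 visitor, 3
  restless), `mu = 2`. Restless days are five 1–2 h agitation bursts
  between 8:00 and 22:00 with a +60/h ambient pacing echo: agitation
  waxes and wanes over a bad day, and the burst-to-routine alternation
  is what distinguishes restlessness from a visitor. Measured over 20
  seeds: day-level sensitivity ~0.92 at false-positive rate ~0.06;
  detection is essentially perfect for away and visitor days and hardest
  for restless days.
* **Micro scenario** — 120 days, 30 with a single 4 h AIA episode
  (half with a heart-rate excursion), 10 visitor days as ambient
  confounders; days split 50/50 (stratified) into fit and held-out
  partitions. Measured over 20 seeds: day-level AUC ~1.0 for G2, ~0.5–0.6
  for G3 (noisy by design), ~0.8 for G1 (weakly informative by design),
  with the fused score matching the best single group.
* **Cohort demo** (`run-all`) — 12 homes x 120 days with varying numbers
  of injected anomalies; runs both tracks per home and summarises weekly
  `rho`, the cohort count correlation, and pooled micro AUCs.

These sizes keep a full run in minutes on one CPU while leaving each
estimate enough data to be stable; `scripts/acceptance.py` averages 5
replicate seeds per scenario and an 8-home cohort.

## Numerical and degenerate-input choices

* K-means stages use seeded initialisation with 10 restarts; all learned
  state (centroids, codebook, scaling, bands) is frozen after training.
* Identical training days collapse to a single day category with a
  warning; a category without verification days borrows the pooled band.
* A constant-valued sensor normalises to zero with a warning; zero IQR
  collapses box-plot fences to [Q1, Q3]; zero MAD flags any value away
  from the median; all-equal samples have medcouple 0 by convention.
* Pearson correlation and weekly `rho` return null (with a warning) when
  undefined rather than raising.
* Unparseable event timestamps are dropped with a logged count; absent
  slots are zero activity, never NaN — data loss is something the macro
  track should *detect*, not impute away.

## Known limitations

* The entropy-rate detector says *that* a day deviates, not *why*;
  distinguishing visitors from decline needs the micro track or external
  information.
* Short (few-hour) agitation episodes are nearly invisible at day scale;
  that separation of scales is the reason the micro track exists.
* Reliability weights are only as good as the cross-validated precision
  estimates; with very few AIA days the fold count shrinks and the
  weights get noisy.
* The fused argmax label is conservative (see above); consumers should
  threshold the fused score for their own sensitivity/specificity
  trade-off.
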