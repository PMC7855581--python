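# Methods

This note records the models, conventions, parameter choices and known
numerical behaviour of the package. Everything quantitative stated here is
computed by the test suite or the examples; nothing is quoted from data the
package does not generate itself.

## Conventions

Time is seconds since the start of the relevant recording; wall-clock
anchoring lives in `TaskSchedule` and is used only to label light/dark
phases (dark 19:00–07:00 by default). Space is centimetres with the origin
at an arena corner. Visit and bout intervals are half-open
`[t_enter, t_exit)` so abutting intervals never double-count. All raw
timestamps within a subject must strictly increase; scorers assume this
and the readers enforce it.

## Discrimination/reversal scoring

An entry is correct when it passes the phase's target entrance (left
during discrimination, right after the reversal at 50.5 h). The FR5
ledger counts correct entries made *after* the 30-entry unrewarded bias
window and flags every 5th as a pellet delivery; total rewards equal
`floor(post-bias correct / 5)` by construction (property-tested).

Entries-to-criterion is the smallest entry index `k >= window` such that
the correct fraction in the trailing `window` (30) entries is at least
`threshold` (0.80). Choices the protocol leaves open, and how they are
fixed here:

* The comparison is inclusive — 24/30 passes. "80% correct" is read
  as >=.
* The criterion is evaluable only once 30 entries exist, so the smallest
  attainable value is 30.
* DL counting starts at the very first task entry, i.e. the bias window is
  included (`count_bias_phase`, configurable); RL counting restarts at the
  reversal.
* The RL1/RL2 day boundary is 24 h after reversal onset, half-open (an
  entry at exactly 24 h is RL2).
* Subjects that never reach criterion are censored at their own total
  entry count — the standard survival treatment — rather than at a global
  maximum.

Reversal errors partition every entry into correct (new target),
perseverative (old target) or neutral (middle); this partition is exact
when the two targets are the outer entrances, and is property-tested.

Kaplan-Meier curves and the Mantel-Cox (log-rank) test are computed with
lifelines; censored subjects shrink the risk set without an event step.

## Y-maze alternation

A visit to arm X opens at the first sample where **both** the nose and the
body center are inside the arm zone — which begins 3 cm into the arm —
and closes at the first sample where either point has left it (the
protocol defines only the opening rule; closure-on-either-exit is this
package's choice and guarantees an intervening non-arm interval before any
re-entry). Tracks are truncated 600 s after their first sample.

The alternation percentage uses overlapping triads sliding by one visit
(`N−2` windows). This convention is what makes the analytic chance level
2/9: conditional on any first visit, the (second, third) continuation is
one of 9 equally likely arm pairs for an unbiased iid visitor, and exactly
2 of them complete a triad with three distinct arms. Non-overlapping triad
variants would not have this chance level and are deliberately not
implemented.

The permutation null shuffles the observed label multiset uniformly
(counts preserved exactly, asserted in tests); its mean converges to the
closed form `100·6·n_A·n_B·n_C / (N(N−1)(N−2))`, about 24.6% ≈ 25% for
near-equal counts — slightly above 2/9 because sampling without
replacement favours label changes.

Two chance levels circulate for this assay: the analytic 2/9 (22.2%) and
the round 25% that permutation analyses of real sequences approximate.
Both are supported; `one_sample_vs_chance` defaults to 2/9 and takes
`chance_pct=25.0` for the other convention. Neither is treated as
canonical.

## Dark-light box

The scoring window is the 600 s after the door opens (60 s after the first
sample by default); the pre-opening dark minute is excluded from all
metrics. In-light holds while the body center is at least 2 cm beyond the
door line, inclusive; the <2 cm corridor counts as dark. Each inter-sample
interval is attributed to the state at its starting sample. Latency is
absent exactly when no light visit occurred. There is no minimum-visit
debounce by default (`min_visit_s = 0`) since the protocol specifies none.
All metrics are invariant under shifting every timestamp by a constant
(tested).

## Activity

Hourly distance is the center-of-gravity path length per wall-clock hour
bin; a movement step is assigned to the bin of its *starting* sample, the
simplest edge rule, which makes bin sums conserve total path length
exactly (tested). Tracking gaps (NaN samples) contribute zero distance —
a gap is not a teleport. Partial edge bins are flagged. The tracker
sampling rate is nowhere asserted; generators default to 12.5 Hz for maze
tracks and 0.5 Hz for multi-day cage tracks, both configurable.

## The synthetic-data generator

The generator's defaults are the study conditions: four genotype x sex
groups of n = 15, a two-day DL phase, reversal at 50.5 h, a 96-h total
task, 10-min maze and box sessions, 2.5-day activity recordings.

**Choice agent.** Entries are emitted by an inhomogeneous Poisson process
(15 entries per dark hour, light phase at 0.2x — chosen to yield several
hundred entries per phase, the scale at which a 30-entry moving window is
meaningful) and chosen by a softmax over entrance values plus a stickiness
bonus:

    P(choice = i) ∝ exp(β·(Q_i + κ·1[i = previous]))
    Q_choice ← Q_choice + α·(reward − Q_choice)

with reward 1 on pellet delivery (the FR5 event, not per-correct-entry
credit — the animal's internal credit assignment is unknowable, so the
observable reinforcer is used; a per-entry shaping variant can be built by
setting `fr=1`). Defaults α = 0.15, β = 8, κ = 0.4, q0 = (0.25, 0.05,
0.05) were calibrated once so that: the first-30-entry bias favours the
left entrance (~0.5 mean); every default agent reaches the DL criterion
within a few hundred entries; perseverative errors drop sharply from RL1
to RL2; and setting `alpha_reversal = 0` produces a censored non-learner.
The family is a minimal generative stand-in able to express those
phenomena, not a claim about murine learning.

**Y-maze walker.** First arm uniform; thereafter repeat the last arm with
`p_repeat`, otherwise complete the alternation with `p_alt`. Expected
alternation is `(1−p_repeat)²·p_alt` in closed form (tested against long
simulations); the iid-uniform null is `p_repeat = 1/3, p_alt = 1/2`.
Defaults (0.15, 0.65) give mid-40s alternation percentages with ~40
visits per 10-min session, a realistic healthy-mouse regime.

**DLB and cage walkers.** The box session is an exponential first-crossing
followed by alternating exponential light/dark bouts, rendered as a track
satisfying the 2-cm geometry; the generator retains the continuous-time
truth, and the sampled scorer agrees with it to within one sample interval
per bout boundary. The cage walk has random headings, wall reflection and
a 3x dark-phase speed multiplier; its per-hour realised displacement is
retained as the binning oracle. Wall reflections clip a few percent of
displacement for fast walkers, so the *recovered* dark/light rate ratio is
slightly below the nominal multiplier (≈2.85 for 3.0) — the scorer is
tested against realised, not nominal, distance.

**Seeding.** Per-subject seeds derive from
`SeedSequence([master, subject_counter, assay_code])`, so cohorts are
bit-reproducible and extensible without reshuffling existing subjects.

What the generator does **not** emulate: biomechanically realistic
trajectories, body-weight and food-deprivation dynamics, inter-batch and
husbandry variation, and tracking noise/dropout beyond explicit NaN gaps.
Passing recovery tests therefore show that the scorers and statistics
faithfully extract what the generative processes put in — not that real
mouse data are this clean.

## Statistics

Measures pass a per-group Shapiro-Wilk gate (α = 0.05): any failing,
too-small (n < 3) or constant group routes the measure to
Kruskal-Wallis + Dunn; otherwise one-way ANOVA + Bonferroni. Planned
contrasts are only the within-sex genotype pairs (m = 2);
Bonferroni-adjusted p is exactly `min(1, 2·p_raw)`. Dunn's z uses joint
ranks with the standard tie correction. The three-way ANOVA on reversal
errors treats day as a crossed factor (it is within-subject in the design;
the crossed analysis mirrors common practice for this assay and is exact
for balanced normal data). Significance threshold 0.05 throughout.

### Known small-sample behaviour

Two calibration facts, measured by this package's own simulations and
worth knowing before trusting p-values near 0.05 at n = 15 per group:

* **Mantel-Cox.** The log-rank chi-square is anticonservative at four
  groups of 15 (~6.5–7% type-I at nominal 5%, shrinking to ~5% by n = 50
  per group). This is a property of the standard chi-square approximation,
  not of this implementation: R's `survival::survdiff` produces the same
  statistic and p-value to six decimals on identical data. The calibration
  test in the acceptance suite documents this by failing a 5% ± 2 SE band
  honestly.
* **Normality-gated comparisons.** Pre-testing normality and then choosing
  ANOVA or Kruskal-Wallis could in principle distort type-I error; the
  measured rate of the full gated pipeline on normal null data (10,000
  replicates during development) is 4.9%, i.e. the gate is benign here.
  On normal data about 19% of replicates route to the nonparametric
  branch (one of four Shapiro tests fails by chance); pass
  `gate="parametric"` explicitly to bypass pre-testing.

The three-way ANOVA's null rejection rate is exactly 5% for balanced
normal data (its F statistic is exactly F-distributed; verified at 200k
replicates against the closed form during development and at 1000
replicates in the suite).

## Problem sizes

Calibration tests use 1000 sequences of length 1000 for the 2/9 chance
level, 10,000 shuffles for the permutation null, 1000 random inputs per
scorer for oracle equivalence, 1000–2000 null replicates for type-I
calibration, and 100 replicate cohorts (60 subjects each) for
reversal-deficit recovery — sizes at which binomial/Monte-Carlo error is
small relative to the tolerances being checked.

## Limitations

* The seventeen composite "key parameters" of spontaneous home-cage
  behaviour, and the short/long shelter-visit threshold derivation, are
  defined by an external analysis platform and are out of scope; the
  module exposes the raw ingredients (hourly bins, visit intervals)
  instead.
* Proprietary tracker file formats are not parsed; inputs are plain
  CSV/TSV exports.
* The dark-compartment assignment of the <2 cm door corridor follows from
  the stated light rule; the original zone layout of the commercial
  tracker cannot be verified from protocol text alone.
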