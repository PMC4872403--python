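# Methods

This note documents the generative model behind the simulated trial, the
defaults and why they were chosen, the numerical conventions of the
statistics module, and what the simulation does and does not establish.

## Adaptive staircase

The program's difficulty control is a 3-down-1-up transformed up-down
staircase on a normalized challenge axis $c \in [0,1]$ per exercise
(0 = easiest). Three consecutive correct responses move difficulty up one
step and reset the counter; any error moves it down immediately. A change
of stepping direction is a reversal: it increments the reversal count and
halves the step size, never below the floor. Defaults: initial challenge
0.1 (difficulty builds up from an easy start), initial step 0.08, step
floor 0.01. The published description of the program names only
"staircase algorithms" holding performance at 75–85 %; the 3-down-1-up
rule was adopted because its theoretical convergence point,
$P(\text{correct}) = 2^{-1/3} \approx 0.794$, sits inside that band and it
is the standard transformed up-down rule for this regime. Steady-state
summaries discard a burn-in of the first 200 trials or the first 6
reversals, whichever is later.

Challenge-to-stimulus conventions (the program gives directions, not
scales): attended-signal exercises map challenge up to target salience
down on [0,1]; both distractor categories map challenge up to
distractor-to-target similarity up on [0,1]; the response-inhibition
exercise maps challenge up to interstimulus time down on a configurable
[0.5, 3.0] s range.

Cross-session persistence is not specified by the program description; the
default here is that an exercise's converged challenge persists across
sessions while the step size (and reversal bookkeeping) resets each
session, so each session re-approaches threshold quickly without
re-climbing from the easy start.

## Exercise registry and scheduling

The registry is fixed: 3 training categories (attended-signal, explicit
distractor, implicit distractor) x 2 modalities x 4 complexity tiers
(visual: Gabor patches, shapes/textures, motion, scenes; auditory: tones,
sweeps, phonemes, words) = 24 two-alternative forced-choice exercises,
plus one visual go/no-go response-inhibition exercise — 25 in total.
The go/no-go exercise is stored at tier 1: it is the only member of its
(category, modality) chain, so it has no unveiling predecessor and is
available from the first session, even though its stimulus content
(complex scenes) is top-of-ladder. Stimuli are abstracted to parameter
vectors (salience / similarity / interstimulus time); no audiovisual
rendering is modeled.

Sessions present at most 7 exercises within 30 minutes; per-exercise block
durations are drawn from {3, 4, 5} minutes subject to the session cap. A
tier-k exercise becomes schedulable only once the same-category,
same-modality tier-(k−1) exercise is complete; completion is 60 trained
minutes (not stated in the program description; chosen so that a fully
compliant 30-hour course can complete all 25 chains with margin). Within
the schedulable set, least-trained exercises go first, ties broken by
exercise id. Each block presents 40 trials (a 3–5 minute block at a few
seconds per trial; the true per-block trial count is not published).
Visual and auditory chains unveil independently. The meta-game wrapper is
reduced to a sessions-to-rank engagement counter; it affects motivation,
not computation.

Full compliance is 60 thirty-minute sessions (30 hours) at 3–5 sessions
per week, within 24 weeks.

## Virtual subjects

Each subject carries traits on the challenge axis — signal_sensitivity,
distractor_suppression (shared by both distractor categories), and
inhibition — plus a lapse rate, per-trait learning rates, a symptom
intercept and noise, and a compliance propensity.

* Response model: $P(\text{correct}) = \gamma + (1-\gamma-\lambda)\,
  \sigma(k(\theta - c))$ with $\gamma = 0.5$ (2AFC and go/no-go),
  logistic slope $k = 8$ on the unit axis. Chosen because it is standard
  and analytically checkable; the real study had human observers.
* Learning: $\theta \leftarrow \theta + r \cdot m \cdot (1-\theta)$ per
  $m$ minutes trained in a category's exercises — monotone, concave,
  saturating at 1. Control-arm game play applies zero trait change by
  default (the emulated study found no control-group change); a placebo
  drift rate is configurable.
* Symptom model: parent-rated total
  $S = \mathrm{clip}(\alpha - \beta\,\theta_d + \varepsilon,\,0,\,54)$,
  rounded; 0–54 is the 18-item x 0–3 rating-scale range. The coupling
  $\beta$ to the distractor-suppression trait is the package's explicit
  generative encoding of the mechanism the training targets; no published
  quantity fixes it, so it is a free generator parameter (see
  Calibration). CGI (1–7) is a noisy monotone recoding of $S$.

Cohort defaults emulate the study population: n = 31, ages Normal(12, 1.9)
truncated to [8, 16], exactly round(15/31 · n) on medication, traits i.i.d.
Beta(2, 3) (mean 0.4 — children starting well below ceiling), lapse
Uniform(0, 0.05), symptom intercept Normal(38, 5) giving baseline totals
near 26, symptom noise SD 2.5 points per visit.

### Calibration of the free generator parameters

Coupling strength, learning-rate scale and heterogeneity have no published
values; they were fixed once, by design, to make the generator's
"effect mode" a clear-effect regime with realistic dispersion:

* learning-rate median 6e-4 per minute: a median completer (~960 distractor
  minutes) gains ~0.2 of trait range, a moderate but visible improvement;
* per-trait learning rates log-normal with log-SD 0.9, independent across
  traits: between-subject spread in training gains is what carries the
  distractor-change/symptom-change correlation, and independence across
  traits keeps attended-signal gains from being mechanically yoked to
  distractor gains (the dissociation the design predicts);
* coupling 30 symptom points per unit trait: a median completer improves
  ~6 points, large against the 2.5-point visit noise;
* embedded probe: 80 fixed-challenge trials (40 distractor-only), so
  binomial counting noise does not swamp the trait signal.

With these values frozen, the default generator yields a positive
distractor-change/symptom-change correlation in ~97 % of replicates
(mean r ≈ 0.6) and the null generator (zero learning, zero coupling)
rejects at ≤ 0.07 across the headline tests — both verified by the
acceptance suite. The real study's outcome values (its effect sizes and
correlation on actual children) are qualitative anchors only; nothing in
the package targets them numerically.

Compliance: dropout is modeled only between baseline and intervention
start (probability 0.1 per subject, matching the study's three
pre-intervention control dropouts in spirit); the configured fraction
(10/21) of trained-arm subjects with the lowest compliance propensity
truncate training at a Uniform(1, 13)-hour draw, mirroring the published
partial-training range; all other subjects complete the full dose.

## Assessments

* CPT: two 10-minute halves of 200 trials (3 s/trial) so the published
  prevalences give exact integer target counts — 45/200 (22.5 %) sustained,
  155/200 (77.5 %) inhibition. The simulated observer uses a saturating
  clipped-linear link (hit probability $0.5 + 0.5\,\theta$, false-alarm
  probability $0.5\,(1-\theta)$, lapse-mixed): unlike the logistic used in
  training, it genuinely reaches ceiling, so a perfect observer scores the
  corrected-rate maximum d'. Hits are driven by signal sensitivity in both
  halves; false alarms by signal sensitivity (sustained half) or the
  inhibition trait (inhibition half).
* d': $z(H) - z(F)$ with the log-linear correction (+0.5 to each cell, +1
  to each denominator) rather than rate clamping — smooth, standard, and
  testable in closed form.
* Span: 48 trials, 12 per load (spatial loads 1/3/5/7, verbal 3/5/7/9),
  6 match / 6 non-match per load for an exact 50 % match prevalence (trial
  counts are not published; these give exact balance). Response time =
  base + slope·load/trait + noise; the metric is mean speed over the two
  highest loads. Accuracy is held stable across timepoints by
  construction, as reported for the instrument, so speed is the only
  moving metric.
* Stroop: simulated at the sheet-count level (three 100-stimulus sheets,
  45 s each), not per-stimulus reaction times. Interference = color-word
  correct − color correct, typically negative; the improvement convention
  (less negative = better) is adopted here and documented rather than
  asserted as the original authors' coding.
* Embedded distractor probe: an 80-trial fixed-challenge (non-adaptive)
  block at training start and end; false positives on the 40
  distractor-only trials are the outcome. Probe hits also yield an
  attended-accuracy secondary measure.
* SWAN screening applies the strict ">" cutoffs (2.11 combined, 2.48
  inattentive, 2.00 hyperactive) on mean item scores.

Schedule: symptom ratings and CGI at baseline / mid (3 mo) / post (6 mo) /
follow-up (12 mo); cognitive tests at baseline and post only; probes at
training start/end. No intervention access between post and follow-up, so
traits — and hence expected ratings — persist unchanged to follow-up.

## Trial engine

Randomization is blocked in batches of eight with a 2:1 target: block
quotas track the running ratio (5:3 and 6:2 alternating at n = 31, final
short block proportional — reproducing a 21:10 split), and the trained-arm
quota within each block is divided between medicated and unmedicated
subjects proportionally, so medication stays approximately balanced across
arms. A single-stratum block degenerates to an unstratified draw with a
warning. How a trailing short block was handled in the original study is
unpublished; proportional splitting is this package's choice.

Arm labels never enter assessment computation — assessments are functions
of latent traits and a generator stream only — mirroring the double-blind
design; an audit test asserts identical outputs for identically
parameterized subjects in different arms.

Per-trial training simulation feeds nothing downstream (learning is
minute-driven; analysis uses assessments, probes and compliance hours), so
the engine offers a summary mode that skips the per-trial log; a test
asserts every other table is bit-identical between modes. Monte-Carlo
loops (type-I calibration at 500 replicates, effect calibration at 200)
use summary mode; single demonstration runs default to full logs.

Seeding: one master seed spawns named substreams (randomization,
compliance, training, assessments) via numpy SeedSequence; (config, seed)
reproduces every CSV byte-for-byte.

## Statistics

All procedures are implemented from their defining formulas; scipy /
statsmodels / pingouin appear only as cross-checking oracles in the test
suite.

* Runs test: one-sided lower-tail p (few runs = separation); exact
  combinatorial null for n+m ≤ 12, else normal approximation with
  continuity correction. Rating scales guarantee cross-sample ties, which
  the classical test excludes; ties are resolved by a stable ordering
  (first sample before second within a tied value) with a warning.
* Friedman: within-block mean ranks, tie-corrected statistic; exact p by
  enumerating all (k!)^n rankings when n·k ≤ 12 and the data are tie-free;
  χ² with k−1 df otherwise. A fully tied matrix returns 0 with p = 1.
* Kruskal–Wallis: tie-corrected H, χ² with g−1 df; all-identical input is
  degenerate (H = 0, p = 1).
* Wilcoxon matched pairs: zero differences dropped (the original policy,
  not Pratt's), mean ranks for tied magnitudes; exact null by dynamic
  programming over sign patterns for n ≤ 25, else normal approximation
  with continuity and tie corrections.
* Levene: center = mean (the original test, not the Brown–Forsythe median
  variant), as named in the analysis plan.
* Mixed ANOVA: standard split-plot decomposition; arm tested against
  subjects-within-arm, measure and interaction against the within-subject
  residual. Change scores enter in raw units (d', seconds, Stroop points),
  as the emulated analysis did. Missing cells raise — the analysis is
  completer-only by design, with no imputation (intent-to-treat analysis
  is explicitly out of scope).
* Effect sizes: Cohen's d with pooled SD, Hedges–Olkin correction
  J = 1 − 3/(4N−9); symptom-change d is oriented control-minus-trained so
  positive favors training.
* No multiplicity correction by default, mirroring per-test reporting; a
  Holm-adjusted column is available behind a flag.
* The adherence-vs-medication diagnostic is reported as a point-biserial
  correlation: the "logistic regression R" named in the emulated analysis
  plan is ambiguous (pseudo-R² variant unstated), so a correlation-scale
  statistic is provided and flagged as an interpretation.

## What the simulation shows — and does not

Passing tests establish that the design's structural constants are
reproduced exactly (registry composition, prevalences, dose bookkeeping,
randomization split, ANOVA df), that the staircase controller holds its
designed band on a known psychometric observer, that every nonparametric
test agrees with brute-force enumeration at small n, and that the analysis
pipeline is calibrated (nominal type-I error under the null generator;
recovery of the built-in effect under the effect generator).

They do not establish anything about real children: virtual subjects have
stationary logistic psychometric functions, no fatigue, motivation,
practice or rater-expectation effects, trait-homogeneous learning within
category, and a one-dimensional linear symptom coupling. The generator's
effect mode is a clear-effect regime for pipeline validation, not an
estimate of the clinical effect size. Stimulus rendering, neural
mechanisms, screening-interview content and recruitment logistics are out
of scope.

## Problem sizes

Default demonstration runs simulate the full design (31 subjects, 60
sessions, 40-trial blocks, ~200k logged trials, ~1 s). Calibration suites
use summary mode: 500 null replicates and 200 effect replicates of the
complete trial-plus-analysis pipeline (~2 minutes together). Exact-test
oracle checks enumerate all instances up to 12 observations per test
family (~1 minute).
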