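# Methods

This note documents the models and procedures implemented in `skillstream`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Pipeline overview

1. **Raw streams.** One trial is a 50 Hz multichannel record: per
   instrument (dominant-hand aspirator, nondominant-hand bipolar forceps) a
   3D tip position (mm), applied force (N) and activation state, plus
   tissue channels — tumor volume removed (fraction, nondecreasing), blood
   volume present (mL, ≥ 0) and healthy-tissue damage (mL, nondecreasing).
2. **Regularization.** Streams are resampled onto an exact 0.02 s grid from
   the first timestamp: continuous channels by linear interpolation (which
   preserves monotonicity), activation states by previous-sample hold.
   Non-increasing or duplicate timestamps are rejected.
3. **Metric extraction.** Sixteen metrics per half-open 0.2 s window (ten
   full windows of raw samples; a trailing partial window is dropped, so a
   trial of *n* raw samples yields ⌊*n*/10⌋ metric rows).
4. **Normalization.** Per-metric z-scores with mean/sd estimated on the
   training subset only and reused unchanged for validation, test and any
   later scoring.
5. **Assessment model.** Two-layer unidirectional LSTM, sequence-to-sequence
   regression onto constant ±1 labels; continuous unclipped score per 0.2 s.
6. **Inverse models.** The same architecture predicting one target metric
   from the other fifteen plus an expertise-level channel, for coaching
   (channel forced to 1) and risk detection (channel set to the performer's
   level code).
7. **Statistics.** One-way ANOVA with Tukey-Kramer post-hoc over group
   participant averages, and OLS of trainee score on year of training.

## The 16-metric set

Ten metrics form the core bimanual feature set: per-instrument mean force,
mean velocity magnitude and mean acceleration magnitude; mean inter-tip
separation; tumor removed; bleeding; and healthy-tissue damage. Six more
are reconstructed from the five-category scheme to reach sixteen and are
flagged `reconstructed` in the manifest: per-instrument path length (movement),
per-instrument active fraction (efficiency), bleeding rate (safety) and
inter-tip relative-velocity magnitude (bimanual cognitive). The extraction
pipeline is parametric in the manifest, so the set can be swapped without
touching the models.

Reduction conventions, fixed and mirrored by the brute-force test oracle:

* velocity is the first difference of position at raw resolution (defined
  from the second sample), acceleration the first difference of velocity
  (from the third); window means average the defined samples;
* path length is the within-window sum of raw step distances;
* cumulative channels (tumor removed, healthy damage) enter as
  end-minus-start deltas over the window so that features are roughly
  stationary in trial time — a constant per-timestep label presupposes
  roughly stationary inputs;
* blood volume is *not* cumulative (aspiration clears it), so its
  per-window delta has near-zero mean regardless of skill; it enters as the
  within-window mean level instead, with a separate bleeding-rate metric
  counting only positive inflow per second.

Units are coherent by construction (N, mm, mm/s, mm/s²); a dimensional
scaling test doubles all positions and asserts that exactly the
length-derived metrics double.

## Assessment model

* **Architecture.** sequence input → LSTM → dropout → LSTM → dropout →
  dense(1) → MSE regression. Hidden width = number of input metrics + 1
  (17 for 16). Both recurrent layers are unidirectional; no attention, no
  bidirectionality — the design is intentionally minimal.
* **Labels.** Every timestep of an expert trial targets +1, of a novice
  trial −1. Under z-scored features these anchors read as one standard
  deviation above/below mean performance, which is why intermediate
  performers land between them and scores are never clipped.
* **Training.** Adam, initial learning rate 1e-3 decayed ×0.1 every 25
  epochs (lr(e) = 1e-3 · 0.1^⌊(e−1)/25⌋), shuffling every epoch, minibatch
  size = ⌊training trials / repeats per person⌋ with a floor of 1. The
  canonical schedule is 1000 epochs; desk-scale runs and the test suite use
  100 (by then the decayed rate is ≤ 1e-6 and weights have long stopped
  moving, so the truncation is cosmetic for these problem sizes).
* **Splitting.** Participants (never trials) are assigned to
  train/validation/test targeting 70/15/15 of trials by greedy
  closest-to-target assignment over a seeded shuffle. All of an
  individual's trials share one subset.
* **Open choices.** Dropout rate is unreported in the source recipe; 0.2 is
  used (conventional, configurable). Padding semantics are likewise
  unreported: variable-length sequences in a minibatch are end-padded to
  the batch maximum and padded steps are masked out of the loss. Gradient
  clipping is off by default with a schedule switch for divergence rescue.
  Train RMSE is reported per epoch from the epoch's minibatch losses;
  validation RMSE from a dropout-free pass after each epoch; test RMSE once
  at the end. A NaN loss aborts with the epoch index.
* **Implementation.** The LSTM, full backpropagation through time and Adam
  are written in NumPy, with the per-timestep recurrences compiled by numba
  when available (a functionally identical vectorized NumPy path is kept as
  fallback). The cell is small enough that this is fast, exactly
  reproducible, and keeps the package dependency-light. Analytic gradients
  are checked against central finite differences in the test suite.

## Scoring and aggregation

One score per 0.2 s metric row; the task average is the plain mean over all
timesteps (no warm-up trimming — the early cold-state steps are visibly
noisier and deliberately left in, since any trimming rule would be
arbitrary). Participant averages are unweighted means over available task
averages; a missing trial simply reduces the denominator (no imputation).
Flagged intervals are maximal contiguous runs of sub-threshold scores as
half-open (start, end) pairs; the default threshold 0 is the midpoint of
the label anchors.

## Inverse models (coaching and risk)

Five models, one per target: aspirator force, bipolar force and tip
separation in coaching mode; blood volume and healthy-tissue damage in risk
mode. Inputs are the 15 remaining z-scored metrics plus one expertise
channel appended as the last input (16 inputs → 17 hidden units by the same
node rule). Targets are learned in z-space and de-normalized on output.
No canonical per-model input list exists for this task family, so
all-metrics-minus-target is used and flagged as reconstructed. Predictions
are concurrent (output at *t* estimates the metric at *t*), not one-step
forecasts. Feedback models train on the expert/novice development pool,
mirroring the assessment model. Risk warnings (a configurable post-step)
flag timesteps where the user-level prediction exceeds the expert-level
prediction by a factor (default 2×), or is positive where the expert
prediction is not.

## Statistics

ANOVA is classical one-way on participant averages; the post hoc is
Tukey-Kramer (the HSD adjusted for unequal group sizes — cohorts here are
14/14/10/12). Assumption checks: Shapiro-Wilk per group and the
median-centered Levene (Brown-Forsythe). Group CIs are t-based intervals on
the group mean (t-intervals are the standard choice). Regression is OLS of score on year of
training with fellows coded year 7. Degenerate inputs (constant response or
constant predictor, groups of one) raise typed errors; all-identical groups
return F = 0 by the sums-of-squares definition.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
tissue physics. Mechanisms (all skill maps affine in a ground-truth skill
s ∈ [−1, 1], directions recorded in `SKILL_DIRECTIONS`):

* tip trajectories = slow purposeful drift (low-frequency sinusoids around
  the tumor site) + Ornstein-Uhlenbeck tremor whose innovation scale falls
  with skill — this drives velocity, acceleration, path length and
  relative-velocity separation;
* the bipolar tip works at a skill-dependent mean offset (11 − 4s mm), so
  tip separation falls with skill;
* forces are nonnegative mean-reverting processes with skill-decreasing
  mean and dispersion (aspirator 0.9 − 0.4s N, bipolar 0.6 − 0.25s N);
* activation is a two-state Markov chain with skill-increasing stationary
  on-fraction;
* bleeding and damage are marked Poisson processes with skill-decreasing
  intensity; blood decays under aspiration, damage accrues irreversibly;
* tumor removal follows first-order kinetics gated by aspirator activation
  and proximity to the tumor site, with a skill-increasing rate constant.

Cohort designs mirror the validation study shape: 14 experts + 12 novices
(156 trials) for development, 14 seniors + 10 juniors (144 trials) for
held-out testing, six trials per participant, trial durations drawn
uniformly from 90–180 s (tests use shorter ranges). Group skill
distributions are truncated normals at ±0.8 (ends, sd 0.1) and ±0.33
(trainee groups, sd 0.15) — the trainee anchors deliberately match the risk
module's level codes. Per-participant skill is drawn once and shared across
that participant's trials; everything is a pure function of (design,
config, seed).

**What passing tests show — and don't.** The generator guarantees monotone,
roughly stationary skill separation in all 16 metrics with Gaussian-ish
noise. Real simulator data has structure the generator omits: task phases
and nonstationarity within a trial, heavy-tailed forces, coupled metric
dynamics, instrument idiosyncrasies, and label noise in group membership.
Recovery of the skill ordering here therefore validates the *mechanics*
(feature extraction, training, scoring, inversion, statistics), not
clinical validity on real cohorts; group means and test statistics
measured on real cohorts cannot be reproduced from synthetic ones and are
not targeted.

## Validation experiment

`skillstream.experiments.expertise_recovery_experiment` is the headline
check: over five replicate seeds, train on a 10+10 development cohort
(60–120 s trials, 100 epochs), then (a) score a held-out nine-rung skill
ladder (skill −1 … +1, six trials per rung) and compute the Spearman rank
correlation between true skill and mean participant score, and (b) score a
held-out four-group cohort and check the ordering expert > senior > junior
> novice of group mean scores. The acceptance bar is mean Spearman ≥ 0.9
and correct ordering in ≥ 4/5 seeds; the last replicate also reports the
four-group ANOVA and a training-year regression over the synthetic trainees
(juniors years 1–3, seniors 4–7).

## Numerical conventions

* z-score standard deviations use the population convention (÷ n), so
  re-applying fitted stats to the training pool gives exactly mean 0, sd 1;
  a metric constant across the training pool raises a degenerate-feature
  error naming the metric (constancy is detected by exact range, which is
  immune to floating-point rounding of the sd).
* Greedy split ties break in the order train > validation > test.
* Window accounting uses sample counts (⌊n/10⌋ windows), so a 120 s trial
  yields exactly 600 rows.
* Forget-gate biases initialize to 1; other weights Glorot-uniform from the
  training seed. Identical seeds and data give bit-identical training runs.
* Oracle-equivalence tests bound the implementation against loop/closed-form
  recomputations at 1e-9 absolute or tighter.

## Known limitations

* The synthetic generator's realism limits, above, are the main one.
* Scores for performers far outside the training distribution are
  extrapolations of an unclipped regressor and can exceed the anchors by
  large margins.
* The recurrent score is warm-up sensitive for the first seconds of a
  trial.
* Inverse-model feedback quality is only demonstrated mechanically
  (level-invariance, hazard ordering, baseline-beating RMSE on constructed
  fixtures); no claim of pedagogical efficacy is made or testable here.
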