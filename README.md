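# skillstream

Continuous assessment of bimanual surgical skill from simulator kinematics.

Surgical simulators record rich instrument streams — tool-tip positions,
applied forces, pedal activation, and tissue state — at 50 Hz, but most
assessment tools reduce an entire procedure to a single summary grade.
`skillstream` implements the alternative: a pipeline that scores technical
expertise **continuously, five times per second**, so feedback can point at
the exact moments of less-skilled performance rather than at the trial as a
whole. It is aimed at surgical-education and simulation researchers who
want a complete, testable reference implementation of this style of
monitoring system, exercised end to end on a built-in synthetic bimanual
simulator (real simulator exports are proprietary and not redistributable).

## The model

Raw streams are regularized onto an exact 0.02 s grid, then reduced to 16
performance metrics per half-open 0.2 s window (per-instrument force,
velocity, acceleration, path length and active fraction; inter-tip
separation and relative velocity; tumor removed, blood volume, bleeding
rate and healthy-tissue damage). Metrics are z-scored with training-set
statistics, and a deliberately minimal recurrent network

    sequence input → LSTM → dropout → LSTM → dropout → dense(1) → MSE

is trained **sequence-to-sequence**: every 0.2 s step of an expert trial
carries target +1, of a novice trial −1. Hidden width follows the fixed
rule *units = number of input metrics + 1* (17 for 16 metrics). Training
uses Adam at 1e-3 decayed ×0.1 every 25 epochs, with minibatch size =
training-trial count ÷ repeats per person, shuffling each epoch, and
participant-grouped 70/15/15 train/validation/test splits so no individual
leaks across subsets. Because targets are anchored one training-set
standard deviation above/below mean performance, scores of unseen
performers fall on (and may exceed) the expert–novice continuum; they are
never clipped.

The same mechanism runs in reverse for feedback: five inverse models
predict one target metric from the other 15 plus an expertise-level input
channel. Coaching models (aspirator force, bipolar force, tip separation)
force that channel to the expert code 1, producing an expert-level target
trajectory; risk models (bleeding, healthy-tissue damage) set it to the
performer's own level code (expert 1, senior 0.33, junior −0.33,
novice −1) to predict hazard trajectories.

The LSTM, backpropagation through time and Adam are implemented in NumPy
(with numba-compiled recurrence kernels); gradients are verified against
finite differences in the test suite.

## Worked example

```python
import skillstream as ss

config = ss.TrialConfig(duration_range_s=(60, 120))

# develop: 10 experts + 10 novices, 6 trials each
dev = [ss.extract_metrics(ss.regularize(s))
       for s in ss.simulate_cohort(ss.development_cohort(10, 10), config, seed=1000)]
results = ss.ExpertiseModel.from_cohort(dev).fit(epochs=100, seed=0)
print(results.summary())

# score a held-out mid-skill performer
trial = ss.extract_metrics(ss.regularize(
    ss.simulate_trial(config, skill=0.3, seed=7)))
scores = results.score(trial)
print(f"task average {scores.task_average:+.3f} over {len(scores)} scores")
print("intervals below 0.5:", ss.timeline_export(scores, threshold=0.5)[:3])
```

prints:

```
Expertise assessment model (sequence-to-sequence LSTM regression)
==================================================================
features: 16   lstm units: 17   dropout: 0.2
layers: sequence_input -> lstm -> dropout -> lstm -> dropout -> fully_connected(1) -> regression(mse)
epochs: 100   minibatch: 14   initial lr: 0.001 (x0.1 every 25)
seed: 0
final train RMSE:      0.2009
final validation RMSE: 0.0859
test RMSE:             0.0835
labels: expert = +1, novice = -1 (per 0.2 s timestep; scores unclipped)
task average +0.650 over 600 scores
intervals below 0.5: [(0.0, 2.6), (5.2, 5.4), (29.6, 32.6)]
```

A task average of +0.65 places this skill-0.3 performer between the novice
(−1) and expert (+1) anchors, closer to the expert end, and the flagged
intervals name the exact time frames that scored below the chosen 0.5
threshold — including the cold-start seconds before the recurrent state has
seen enough of the trial. A full command-line front end
mirrors the library (`skillstream simulate|extract|train|score|coach|risk|
validate|pipeline`).

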