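# Methods

## Problem and model

Given a multichannel IMU recording sampled at a working rate of 50 Hz
(one frame = 20 ms), the forecaster maps the past `p` samples of all
`N = 63` sensor channels to the next `f` frames of a target quantity.
Two tasks share the architecture:

* **trajectory** — the sagittal-plane angular velocities of the
  ipsilateral thigh, shank and foot (D = 3 continuous outputs per frame,
  in z-score-normalized units);
* **phase** — one of five gait phases per frame (LR, MS, TS, PSw, Sw),
  derived as ground truth from bilateral foot switches.

The network is a single LSTM layer whose width is `units_multiplier · f`
(default multiplier 5), followed by `f` parallel dense heads; head `i`
emits frame `t+1+i`.  Trajectory heads are linear, phase heads softmax.
Predicting all frames in one shot avoids the error accumulation of
autoregressive single-step rollout.  Stacked LSTM layers are supported
(`n_layers`) and grid-searchable, but one layer is the default.

### Loss

The training criterion is a discount-weighted sum of per-frame losses
plus an L1 penalty:

    L = mean_w [ Σ_{i=0}^{f−1} α^i ℓ_i ] + λ Σ |W|

with `ℓ_i` the squared error (trajectory) or categorical cross-entropy
(phase) of frame `i`.  Implementation conventions, fixed once:

* the discount weight of frame `i` is `α^i` with `i` starting at 0, so
  the first predicted frame always has weight 1 (and `0^0 = 1`);
* the data term is averaged over the windows of a batch and the penalty
  added once per batch;
* the L1 penalty covers all weight matrices and excludes biases;
  `λ = 1e-4` by default;
* cross-entropy clips probabilities at `p_floor = 1e-12` to avoid
  `log 0`.

Defaults: `α = 0.8` for trajectory (sharpens the most immediate frames),
`α = 1.0` for phase (softmax classification is insensitive to the
discount; the argmax rarely changes).

### Optimisation

Mini-batch Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 128,
at most 100 epochs with early stopping when the validation loss has not
improved for 10 consecutive epochs; the best-epoch weights are restored,
which makes the returned model a deterministic function of the config
seed.  Gates use a fused `[input, forget, cell, output]` weight layout
with forget-gate biases initialised to 1; other parameters are
Glorot-uniform from a generator seeded by `config.seed`.  Backpropagation
through time and Adam are implemented directly on NumPy arrays; the
analytic gradients are verified against central finite differences in
the test suite.  An exhaustive `grid_search` helper evaluates candidate
configs on an internal validation split (lowest RMSE for trajectory,
highest accuracy for phase; ties keep the first grid point).

## Preprocessing

* **Down-sampling** (e.g. 2000 → 50 Hz): zero-phase 4th-order Butterworth
  low-pass at 0.4 × target rate, then every k-th sample.  The cutoff
  keeps the pass band comfortably inside the new Nyquist frequency.
  Binary foot-switch channels are instead decimated by majority vote
  within each k-sample block, ties resolved to "on" — filtering a binary
  signal is meaningless.  Output length is `floor(M/k)`.
* **Normalization**: per-channel z-score with the population variance
  convention (divide by n), sd floored at `1e-8` for constant channels.
  Parameters are fitted on training data only and applied unchanged to
  test data; fitting them globally would leak test statistics through
  the channel means.  Whether to fit per subject, per speed or globally
  is genuinely open; the protocols fit per training pool (per subject
  in the intra protocol, per leave-one-out pool in the inter protocol),
  the most conservative choice available in each design.

## Phase labeling

Foot contact is the first sample where any of the four switches turns on
after an all-off period; heel off the first sample where the heel switch
turns off while a forefoot switch remains on; foot off the first sample
where all four are off.  This is the minimal reading of the switch
semantics.  Cycles are anchored at consecutive ipsilateral foot
contacts, and the five phases are assigned on half-open intervals
(start inclusive) so every sample has exactly one label — boundary
ownership is otherwise arbitrary.  Samples outside complete cycles are
marked unlabeled and windows whose target span touches them are dropped.
Switch traces are debounced first (runs shorter than 2 samples = 40 ms
are merged into their neighbours; configurable).  Contralateral events
come from the contralateral foot's own trace, not from mirroring.

## Windowing

Stride-1 sliding window by default: window `w` pairs inputs
`[start, start+p)` with targets `[start+p, start+p+f)`; the count is
`floor((M−p−f)/slide)+1`.  The standard configurations are `(p, f) =
(10, 5)` for 100 ms and `(30, 10)` for 200 ms ahead.  Trajectory targets
default to the 3 evaluated channels rather than all 63: the evaluation
only ever scores those three, and a 3-output head trains faster; the
target set is configurable (e.g. all 21 angular-velocity channels).
Which local gyroscope axis is the sagittal-plane (mediolateral) one
depends on mounting and is a configuration mapping; the default is the
z axis at every site.

## Evaluation protocols

* **Intra-subject**: per subject, pool all 5 speed conditions, window,
  split windows randomly 70/30 (reproducible from `split_seed`), train
  on 70 %, report on 30 %.  The split is at the window level because the
  model consumes windows; adjacent-window overlap across the split is
  accepted, as a random split implies.
* **Inter-subject**: for each subject, train on the pooled windows of
  all other subjects and test on every window of the held-out subject.
  Provenance tags on each window are asserted at run time so no held-out
  window can enter its own training pool.

15 % of each training pool is reserved for early stopping.  Reports
(JSON-serializable, round-trip tested) hold per-segment trajectory
metrics, per-frame MAE curves, per-phase signed-error boxplot statistics
(quartiles by linear interpolation — the inclusive convention; whiskers
at the most extreme points within 1.5 × IQR), and for the phase task
accuracy, recall and confusion counts.  Pearson R and SNR pool all
predicted frames of a channel; an exact prediction yields an infinite
SNR, reported as a sentinel and displayed as 99 dB in text output.

## Synthetic data

No gait dataset is bundled, so the generator emulates the acquisition:
each of the 63 channels is a sum of `n_harmonics` (default 4) harmonics
of the stride frequency with subject-specific random amplitudes and
phases (decaying spectrum; magnetometer channels keep only a small
fundamental), scaled per modality, plus white noise whose sd is
`noise_sd` times the channel's own signal sd.  The default per-subject
cycle duration is drawn from 0.98–1.07 s, the adult range; five speed
levels scale the stride frequency by 0.8–1.2; per-cycle duration jitter
(fractional sd 0.02) makes the signals quasi-periodic.  Foot switches
are driven by the same cycle clock: heel on from foot contact to heel
off, forefoot switches on shortly after contact until foot off, and the
contralateral foot is the ipsilateral pattern shifted by exactly half a
cycle.  That half-cycle symmetry constrains the phase fractions to
`MS + TS + PSw = 0.5`; the defaults (0.10, 0.20, 0.20, 0.10, 0.40)
satisfy it and match standard gait-phase proportions.

What the generator does *not* emulate: biomechanically realistic
waveform shapes, left/right asymmetry, non-stationarity across a
session, soft-tissue artefacts, or inter-channel correlation structure
beyond shared stride phase.  Passing tests on this cohort therefore
demonstrate that the pipeline, model and protocols behave correctly on
quasi-periodic multichannel signals — not that any particular accuracy
level transfers to human subjects.

## Problem sizes used in the shipped checks

The end-to-end checks run on a cohort of 4 subjects × 5 speeds × 60 s
(≈ 15 000 windows per subject at 50 Hz) with `noise_sd = 0.05` and the
100 ms configuration `(p, f) = (10, 5)`, training for at most 40 epochs
with patience 10 — on this cohort the validation loss plateaus well
before that cap.  Seed-averaged checks (per-frame MAE monotonicity,
discount-factor effect on the first frame) use one subject at the middle
speed with 3 and 5 seeds respectively.  These sizes are the package's
standard small-study configuration; all of them are generated at run
time.

## Known limitations

* The LSTM runs on NumPy; it is single-threaded-friendly but not
  GPU-accelerated, and very large cohorts train slowly.
* Inter-subject generalisation on the synthetic cohort is intentionally
  hard (subjects have independent random channel parameters), so
  inter-protocol errors are much larger than intra — the directional
  relation matches the expectation, the magnitude is not meaningful.
* No statistical significance testing across subjects is provided.
* Swing is never sub-phased, and incomplete cycles at recording edges
  are excluded rather than extrapolated.
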