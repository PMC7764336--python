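# gaitcast

Multi-frame forecasting of lower-limb gait trajectories and gait phases
from wearable inertial sensors.

Powered exoskeletons with phase-based control need to know where the leg
will be a few hundred milliseconds from now: control loops, motors and
mechanical sensors all add delay. `gaitcast` predicts, from a window of
the past `p` samples of a 63-channel IMU array (7 sensor sites × 3-axis
acceleration, angular velocity and magnetic field), the next `f` frames —
up to 200 ms at the 50 Hz working rate — of

* the **gait trajectory**: sagittal-plane angular velocities of the
  ipsilateral thigh, shank and foot, and
* the **gait phase**: loading response (LR), midstance (MS), terminal
  stance (TS), pre-swing (PSw) and swing (Sw), labeled automatically from
  bilateral foot switches.

## Model

All `f` future frames are predicted simultaneously (no autoregressive
rollout, so single-step errors cannot compound).  A single LSTM layer of
`5·f` units consumes the `p × N` input window; its final hidden state
feeds `f` parallel dense heads, head `i` emitting frame `t+1+i` (linear
for trajectory, softmax over the five phases for classification).
Training minimises a discount-weighted multi-output loss

```
θ* = argmin_θ  Σ_{i=0}^{f−1} α^i · ℓ(y_{t+1+i}, ŷ_{t+1+i})  +  λ Σ|θ|
```

where `ℓ` is squared error or categorical cross-entropy, the discount
factor `α ∈ [0,1]` concentrates learning on the immediate frames
(default 0.8 for trajectory, 1.0 for phase), and the L1 term sparsifies
the weights.  The network, backpropagation through time and the Adam
optimiser are implemented directly in NumPy.

Two evaluation protocols are built in: **intra-subject** (per subject,
pool all treadmill speeds, random 70/30 window split) and
**inter-subject** (leave-one-subject-out).  Metrics: signed mean error,
MAE, RMSE, Pearson R and SNR in dB for trajectories; accuracy, per-phase
recall and confusion matrices for phases.

Because no public dataset accompanies the method, the package ships a
synthetic-gait generator (`gaitcast.synthetic_data`) producing
quasi-periodic 63-channel recordings with foot-switch traces that follow
the canonical event sequence, so the full pipeline is testable offline.

## Worked example

```bash
gaitcast simulate --subjects 2 --duration 30 --seed 1 --out sim/
gaitcast eval-intra --data-dir sim/ --task trajectory --horizon 5 \
    --epochs 40 --seed 0 --out report/
```

prints (numbers from this exact invocation):

```
thigh RMSE 0.093 R 0.996
shank RMSE 0.091 R 0.996
foot  RMSE 0.094 R 0.996
report written to report/report.json
```

i.e. on held-out 30% windows of each synthetic subject, the predicted
100 ms of thigh/shank/foot angular velocity correlates with the true
trajectory at R ≈ 0.996 with an RMSE of ≈ 0.09 in z-score units.  The
JSON report also contains per-frame MAE curves (monotonically increasing
with prediction distance), per-phase error boxplot statistics, and — for
`--task phase` — confusion matrices and per-phase recall.

The same pipeline is available as library calls:

```python
import gaitcast as gc

spec = gc.SyntheticGaitSpec(n_subjects=4, duration=60.0, seed=0)
cohort = gc.generate_cohort(spec)
config = gc.ForecastConfig(p=10, f=5, alpha=0.8, task="trajectory")
report = gc.run_intra(cohort, config, split_seed=0)
print(report.mean_metric("shank", "r"))
```

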