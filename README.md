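# taylorbp

Physics-informed (Taylor-consistency) neural networks for **beat-to-beat
cuffless blood-pressure estimation from wearable bioimpedance**, with a
minimal-label training protocol, the full signal-processing pipeline, and
a synthetic bioimpedance/BP simulator that makes every stage testable
without access to recorded data.

## The problem

A bioimpedance sensor over an artery sees a quasi-periodic impedance
change (ΔZ) as each pressure pulse swells the vessel. Mapping that signal
to systolic/diastolic/pulse pressure (SBP/DBP/PP) per beat normally
requires training on thousands of cuff-reference labels per wearer —
burdensome to collect. This package implements a training scheme that
needs roughly one label per mmHg of BP range (a few dozen beats): the
network's loss gains a *Taylor-consistency* term computable on unlabeled
beats.

For each beat i with waveform x⃗ᵢ and physiological features
u⃗ᵢ = (u¹, u², u³) — amplitude drop (ΔZ)_A − (ΔZ)_C, inverse
systolic-to-reflection delay 1/(t_F − t_B), and heart rate
60/(t_J − t_A) — the model f(x⃗, u⃗; Θ) is expanded to first order around
beat i and evaluated at beat i+1:

    P_i(u⃗) = f(x⃗_i, u⃗_i) + Σ_k ∂f/∂u^k |_i · (u^k − u_i^k)
    h_i     = f(x⃗_{i+1}, u⃗_{i+1}) − P_i(u⃗_{i+1})

Because cardiovascular state drifts slowly between consecutive beats,
h_i should be near zero; the training loss is

    L = α · MSE(labeled beats) + β · mean(h_i²),   α = 1, β = 10.

Setting β = 0 recovers the conventional CNN baseline with the identical
architecture (Conv1D 32×5 → Conv1D 64×3 → max-pool 3/1 → flatten →
concat u⃗ → Dense 60 → Dense 1). Training stops when the supervised loss
reaches 0.01 (normalized units). Gradients ∂f/∂u⃗ come from the package's
own reverse-mode autodiff engine and double as an interpretability
readout (e.g. the learned ∂y/∂u¹ is negative under vasoconstriction-like
amplitude coupling).

## Worked example

```python
import numpy as np
from taylorbp import SimConfig, generate_subject, preprocess_subject
from taylorbp import minimal_split, TaylorPINNRegressor
from taylorbp.protocols import prepare_dataset, nonlinear_subject
from taylorbp.metrics import compute_metrics, aami_grade

ds = prepare_dataset(nonlinear_subject(seed=100))   # ~195 beats, SBP 120-134
sbp = ds.y[:, 0]
split = minimal_split(sbp, bin_width=1.0, seed=0)   # 1 label per mmHg bin
print(f"labels: {split.n_train} train / {split.n_test} test")

y_fit = np.where(np.isin(np.arange(len(sbp)), split.train_idx), sbp, np.nan)
X = np.hstack([ds.x, ds.u])                          # [waveform | u1 u2 u3]
est = TaylorPINNRegressor(alpha=1.0, beta=10.0, max_epochs=1200,
                          random_state=0).fit(X, y_fit, sessions=ds.session)

pred = est.predict(X[split.test_idx])
report = compute_metrics(pred, sbp[split.test_idx])
print(f"ME {report.me:+.2f}  SDE {report.sde:.2f}  RMSE {report.rmse:.2f} mmHg"
      f"  r {report.pearson_r:.3f}  grade {aami_grade(report)[0]}")
```

Output:

```
labels: 14 train / 181 test
ME +0.19  SDE 2.71  RMSE 2.71 mmHg  r 0.926  grade A
```

i.e. with 14 labeled beats (≈7 % of the record) the PINN tracks the held
-out beats to below 3 mmHg on this synthetic subject; `est.feature_gradients(X)`
returns the per-beat ∂y/∂u⃗ whose u¹ component is negative, matching the
simulator's configured amplitude coupling.

The same flow is available from the shell:

```bash
taylorbp simulate   --out-trace t.csv --out-labels l.csv --seed 5
taylorbp preprocess --trace t.csv --labels l.csv --out store.h5
taylorbp train      --store store.h5 --target sbp --beta 10 --out model.npz
taylorbp evaluate   --ckpt model.npz --store store.h5 --report report.json
```

`preprocess` accepts any CSV trace with columns `time_s,delta_z` plus a
beat-label CSV (`beat_index,onset_s,SBP,DBP,PP,session`), so recorded
bioimpedance datasets can be run through the identical pipeline.

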