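# Methods

`taylorbp` estimates beat-to-beat blood pressure (systolic, diastolic or
pulse pressure; one model per target) from single-channel bioimpedance
(ΔZ) and trains that estimator with very few labels by adding a
Taylor-consistency ("physics") term to the loss. This note records the
model, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Model

Each cardiac cycle contributes two inputs: the segmented beat waveform
x (resampled to 30 Hz, zero-padded to a fixed length N) and a feature
triple

- u¹ = (ΔZ)_A − (ΔZ)_C — the pulse amplitude drop between cycle onset
  and systolic peak, a proxy for arterial volume excursion;
- u² = 1/(t_F − t_B) in s⁻¹ — the inverse delay between the maximum
  systolic slope and the reflected-wave peak, a pulse-wave-velocity
  proxy (PWV = √(Eh/Dρ) rises with wall elastic modulus, hence with BP);
- u³ = 60/(t_J − t_A) in bpm — the beat-to-beat heart rate.

The regressor f(x, u; Θ) is a two-layer 1-D CNN over x (32 filters of
width 5, then 64 of width 3, both ReLU, valid padding), max-pooled
(size 3, stride 1) and flattened, concatenated with u, then passed
through a 60-unit ReLU layer to a linear scalar head. All inputs and the
output are z-scored; predictions are mapped back to mmHg.

### Taylor-consistency loss

Cardiovascular state drifts slowly across consecutive beats, so the
model's own first-order expansion around beat i,

P_i(u) = f(x_i, u_i) + Σ_k ∂f/∂u^k |_i (u^k − u_i^k),

evaluated at beat i+1 should agree with the model's prediction there.
The residual h_i = f(x_{i+1}, u_{i+1}) − P_i(u_{i+1}) vanishes as beat
i+1 approaches beat i; its mean square over all R−1 consecutive
same-session pairs is the physics loss. It uses no labels, so every
unlabeled beat constrains training (a transductive term). The total loss
is

L = α·MSE(labeled beats) + β·mean(h_i²),  α = 1, β = 10,

which at initialisation puts the supervised term roughly an order of
magnitude above the weighted physics term, so the label scale anchors
early training and the consistency constraint dominates the endgame.
Pairs never straddle session boundaries: the slowly-varying premise
holds within a recording, not across gaps.

An optional second-order mode adds ½ Δuᵀ H_i Δu to the polynomial. With
the (default) ReLU head, f is piecewise linear in u and H ≡ 0 almost
everywhere, so order 2 differs from order 1 only for the smooth (tanh)
head option; the implementation is exact in both cases.

### Differentiation strategy

No deep-learning framework is used; the package carries a small
vectorized reverse-mode autodiff engine (`taylorbp.autodiff`). Because u
enters only through the dense head, the feature gradient has the closed
form ∂f/∂u = W₂ · diag(σ′(z₁)) · W₁ᵘ. That expression is itself built
from graph primitives (with σ′ detached for ReLU, where it is piecewise
constant, and in-graph for tanh), so a single reverse sweep
differentiates the physics loss — which contains ∂f/∂u — with respect to
Θ, with no nested autodiff. A finite-difference test over the full
weight vector of a tiny model verifies the combined path.

## Training protocol

- Optimizer: full-batch Adam, step 1e−3 (β₁ 0.9, β₂ 0.999). The choice
  is recorded in `TrainConfig` and logged.
- Stopping: training ends when the *supervised* loss reaches 0.01 in
  normalized units, the same rule for PINN and the β = 0 baseline; an
  epoch cap (default 5000) is a safety net and warns when hit. On data
  with heavy beat-to-beat variability the physics term resists forcing
  the supervised loss to 0.01 — that resistance is the intended
  anti-overfitting behaviour, and such runs end at the cap.
- β = 0 *is* the conventional CNN trainer: the physics computation is
  skipped and the trajectory is bit-reproducible under a fixed seed.
- Minimal-label split: bin the labels at 1 mmHg over their range (K =
  range bins; empty bins contribute nothing) and draw one random beat
  per populated bin — e.g. 1000 beats spanning 120–160 mmHg yield 40
  training and 960 test samples. The growing-label experiment uses
  0.5 mmHg bins and trains models on cumulative pools of 1, 3, 5, …
  points.
- Normalization statistics default to the full per-subject dataset
  (features individually, outputs per target); fitting on the training
  subset only is available by passing that subset, since the full-data
  convention leaks test statistics by construction.

## Synthetic data generator

The generator (`taylorbp.simulate`) emits ΔZ traces from a known latent
BP trajectory so that every pipeline stage has an exact oracle. Each
beat of the inverted waveform is a sum of closed-form cosine lobes:
a systolic rise (half-width 0.14 s) to peak amplitude A_k, a fall to a
diastolic plateau at 0.45·A_k, a symmetric reflected-wave bump (relative
amplitude 0.45) peaking exactly at onset + 0.14 s + d_k, and a pre-onset
dip shaped as the time-reversed systolic rise truncated at the plateau.
The dip makes the valley around each onset locally an even function, so
the zero-phase 6 Hz filter does not displace the onset's derivative
zero-crossing — this is what lets the segmentation contract be stated at
±1 sample.

Latent couplings (all configurable, defaults in `SimConfig`):

- amplitude A_k falls with SBP (a₁ = −0.01 ΔZ/mmHg linear, or a
  saturating tanh variant with 25 mmHg scale emulating pressure-dependent
  compliance) — the vasoconstriction analogue;
- reflection delay d_k falls with SBP (a₂ = −1 ms/mmHg) — the PWV
  analogue;
- heart rate rises 0.25 bpm/mmHg below a breakpoint and falls
  0.2 bpm/mmHg above it — the biphasic CPT response.

Because the landmarks are exact, the noise-free features are closed
forms (u¹ = A_k, u² = 1/(d_k + 0.07 s), u³ = HR_k) and the gradients
∂SBP/∂u follow from the inverse-function rule; a configuration whose
couplings are not single-valued over the realised range (e.g. the HR
breakpoint crossed) is rejected rather than given an ill-defined
gradient.

Optional variability emulates features of real recordings that the BP
labels do not explain: white per-beat jitter of amplitude/HR/delay,
respiratory modulation (0.25 Hz) of amplitude and HR, and additive white
Gaussian trace noise. Labels remain exact; the latent state records the
*realised* per-beat values, so oracles stay clean. Not modelled: motion
artifacts, electrode drift, multi-channel geometry, or any
arterial-tree mechanics — the generator is phenomenological, and
quantitative realism is not claimed.

## Canonical validation subjects (`taylorbp.protocols`)

- *Linear subject*: noise-free, one CPT/recovery cycle (120→150→120
  mmHg over 240 s, ≈270 beats). Used for the segmentation/feature
  oracle (onsets within ±1 sample, features within 2 %) and for
  end-to-end sanity (an affine feature-BP map is exactly representable
  by a first-order-consistent model).
- *Nonlinear subject*: two CPT/recovery cycles peaking at 134/132 mmHg
  (saturating compliance coupling, HR breakpoint inside the range),
  10 % amplitude jitter, 2 %/3 % HR/delay jitter, respiratory
  modulation, 2 % trace noise; ≈195 averaged beats, a ≈14 mmHg SBP
  range, hence a minimal-label budget of roughly a dozen beats. These
  conditions give the conventional CNN something real to overfit —
  label beats whose features are jitter-displaced — while the
  consistency term, which any smooth map of u satisfies but
  beat-specific memorisation violates, resists. The PINN-vs-CNN
  comparison and the gradient-sign recovery run here.

Passing these synthetic checks shows the machinery is correct and that
the consistency term confers the intended robustness *under the
generator's assumptions*; it does not certify accuracy on real
bioimpedance, where artifact structure, sensor drift and inter-subject
variation are outside the simulator's scope.

## Numerical and design choices

- Filtering is forward-backward (zero-phase) so timing features carry no
  phase bias.
- Beat windows are half-open [onset, next onset) in 0-based samples;
  record-edge beats (no confirmed preceding zero-crossing, or no
  following onset) are excluded.
- Landmark *times* are located on the filtered beat (sub-sample parabolic
  refinement for B, C, F); *amplitudes* are read off the raw beat at
  those locations, so the 6 Hz low-pass does not attenuate u¹.
- Segmentation periodicity: derivative peaks at ≥0.6 of the coarse
  (high-threshold) median interval, heart-rate band 20–250 bpm,
  configurable; weaker peaks closer than half the median interval are
  dropped.
- Padded length N = ⌈95th-percentile beat duration × 30 Hz⌉ per dataset,
  recorded in the store; longer beats are dropped with a warning naming
  the required N.
- The three-beat moving average (stride 2, so consecutive windows share
  exactly one beat) runs after resampling, on equal-length vectors;
  features are averaged rather than recomputed from averaged waveforms
  (the alternative reading is available by disabling smoothing and
  averaging externally).
- Fiducials beyond A, B, C, F, J are detected as labelled extrema of the
  beat and its derivative and carried as metadata only; a beat whose
  required landmarks cannot be ordered is flagged feature-incomplete,
  never fabricated.
- AAMI-style grading thresholds (|ME| ≤ 5, SDE ≤ 8 mmHg for grade A)
  come from the device standard, not from measurements here; they are
  configuration, with a provenance note in the code.
- Checkpoints are plain `.npz` archives (config JSON + weight arrays)
  restoring bit-exactly.

## Known limitations

- The simulator's beat morphology is stylised; fiducial detectors tuned
  to it may need re-tuning for real waveforms (prominence/height
  thresholds are exposed).
- Second-order consistency is a no-op for the default ReLU head (exact
  zeros), matching the theory but making the order comparison
  informative only for smooth heads.
- Training is full-batch and CPU-bound; problem sizes in the tests
  (hundreds of beats, ≤ a few thousand epochs) were chosen so the whole
  validation suite runs on one core. Larger datasets would want the
  mini-batched physics term (available via configuration) and a compiled
  backend.
- Inter-subject transfer (training on a cohort, calibrating to a new
  wearer) is out of scope; all protocols here are within-subject.
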