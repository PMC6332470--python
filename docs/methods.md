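# Methods

## Neuron model

The adaptive spiking neuron (ASN) is a spike-response model simulated as a
discrete-time dynamical system. Four exponential traces make up the state:

* `psc` — postsynaptic-current trace, decay τ_β;
* `s` — the activation S(t): `psc` passed through the membrane filter, decay τ_φ;
* `s_hat` — refractory sum Ŝ(t), decay τ_η, incremented by the instantaneous
  threshold ϑ(t) at each spike (η(0) = 1);
* `theta_trace` — adaptive threshold component, decay τ_γ, incremented by
  m_f·ϑ0·ϑ(t) at each spike, so ϑ(t) = ϑ0 + theta_trace and the threshold
  grows multiplicatively under sustained drive.

A spike is emitted when V = S − Ŝ exceeds **ϑ(t)/2**. The half-threshold
comparator implements mid-tread quantization of the signal (each spike
"transfers" one threshold quantum; firing when the residual exceeds half a
quantum keeps the tracking error within ±ϑ/2) and is consistent with the
`+h/2` term of the transfer function below. With m_f = 0 the threshold is
constant and the model reduces to a fixed-threshold SRM0 /
leaky-integrate-and-fire sigma–delta encoder. Ŝ then tracks the rectified
activation, so non-positive constant inputs never spike.

Updates use exact per-step decay factors `exp(−dt/τ)` — the kernels are
pure exponentials, so no Euler error is introduced. Within a step the order
is: decay traces → integrate input → evaluate the spike condition → apply
spike effects. At most one binary spike per step. Both input filters are
DC-gain normalized, so a constant injected current equals the steady-state
activation it produces.

### Default parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| ϑ0 | 0.05 | – | resting threshold; the precision/rate dial |
| m_f | ϑ0/2 | – | adaptation speed |
| τ_γ | 15 | ms | adaptation-kernel decay |
| τ_φ | 5 | ms | membrane filter decay (50 ms in the readout layer) |
| τ_η | 50 | ms | refractory-kernel decay |
| τ_β | 50 | ms | postsynaptic-current decay |
| h | normalized | – | per-spike postsynaptic scale, set so f(1) = 1 |
| dt | 1 | ms | simulation step |

Time constants are in the range observed for cortical neurons. When τ_η is
varied (rate/latency trade-off experiments), τ_β is varied with it: the
refractory kernel and the PSP it mirrors describe the same per-spike
signal quantum.

## Transfer function and its calibration

For constant S the coding loop settles into periodic firing and the mean
postsynaptic contribution is

    f(S) = max(0, h/(exp(g(S)) − 1) − c0 + h/2),   g(S) = (c1 S + c2)/(c3 S + c4)

with c1 = 2·(m_f ϑ0)·τ_γ², c2 = 2·ϑ0·τ_η·τ_γ,
c3 = τ_γ·((m_f ϑ0)·τ_γ + (2·m_f ϑ0 + 1)·τ_η), c4 = ϑ0·τ_η·(τ_γ + τ_η), and
c0 = h/(exp(g(ϑ0)) − 1), which gives the identity f(ϑ0) = h/2. Since c0 is
linear in h, the normalization f(1) = 1 has the closed form
`h = 1/(inv(1) − inv(ϑ0) + 1/2)` with `inv(x) = 1/(exp(g(x)) − 1)`; it is
exact to machine precision for every ϑ0 in the operating range
[0.015, 0.5]. f's analytic derivative (zero on the clipped branch,
left-continuous at the boundary, standard rectifier practice) is what the
trainer backpropagates through. Left of the pole of g the rectifier is
identically zero, so `f_S` evaluates to 0 there rather than raising; the
validity of the denominator on the operating range [0, 10] is checked when
the constants are built.

Three low-level conventions in the discrete simulation are not derivable
from the formulas alone — the algebraic form of the per-spike threshold
increment, the spike comparator, and the normalization of the PSP kernel
κ = PSC ⊛ φ. We fixed all three **empirically against f(S)**, which is the
quantity conversion relies on: simulating a single neuron at constant S
over ϑ0 ∈ {0.05, 0.1, 0.25} and a 20-point grid in (ϑ0, 2], the
combination (increment m_f·ϑ0·ϑ(t), comparator V > ϑ/2, per-spike PSC kick
of **h/2**) reproduces the analytic curve with ≤ 3.9% relative error
(median ≈ 0.5%), stable across τ_η ∈ {25, 50, 100} ms; every other
combination deviates by 40% or more. The h/2 kernel scale (kernel time
integral (h/2)·τ_β) is therefore the shipped default (`psp_norm =
"transfer"`); peak-normalized (`"peak"`, one PSP peaks at exactly h) and
full-kick (`"psc"`) conventions remain available, as do the alternative
comparator and increment readings, behind `ASNParams` switches. The
residual ≲4% error is largest just above ϑ0, where intervals are long and
the 1 ms discretization of the threshold crossing matters most.

## Conversion

Analog networks use f as activation ("adaptive artificial neurons"). At
conversion every unit becomes an ASN with shared parameters; h scales the
per-spike postsynaptic impact, never the stored weights. Rewrites:

* **BN folding** — exact affine absorption into the preceding layer's
  weights/bias (ε as stored with the network, default 1e-3); function
  preservation is asserted to 1e-6 over random inputs.
* **Input encoding** — one ASN per feature, driven by the (standardized)
  feature value as injected current; the standardization statistics live on
  the input layer and apply identically in the analog reference.
* **Pooling merge** — a pooling layer is merged into the next spiking
  layer, which first filters incoming spikes into per-unit analog traces,
  pools those (max ties break to the first index; pooling the decoded
  traces mirrors analog pooling of activations because f is monotone), then
  applies its weights and spikes.
* **Biases** add to the filtered activation S directly; they are constants,
  not synaptic events.
* **Readout** — the last layer integrates weighted spikes with a slow
  membrane filter (τ_φ = 50 ms), adds its bias, and never spikes; softmax +
  argmax at every step is the running classification.

## Metrics

Evaluation presents each input persistently for T = 500 ms at dt = 1 ms.
Matching time (MT) is the first time the aggregate classification error
over the evaluated set reaches 101% of its window minimum (aggregate, not
per-image — it describes the error-vs-time curve of the classifier).
Firing rate averages spikes per spiking neuron (input + hidden; the
readout does not spike) per input per second over the full window; NoS and
synaptic operations (spikes × outgoing synapses of the emitting neuron)
are counted up to MT and averaged per input. Both counting windows are
explicit fields of `EvalMetrics`. Trade-off curves (τ_η sweep, graceful
degradation) are measured over the full 240-sample dataset rather than the
60-sample test split: MT is read off an error trace whose resolution is
1/n, and 60 samples quantize it too coarsely for monotonicity comparisons.

## Arousal

`ArousalConfig` holds the two precision levels (defaults ϑ0 = 0.3 low /
0.06 high), the accumulation start t_sa = 150 ms and window 50 ms, and the
linear threshold schedule θ_A(t) = p1·(t − t_sa) + p2. Margins accumulate
the per-step difference between the winning and second readout activation;
the winner is re-ranked each step by default (well defined when the leader
changes mid-window; a fixed-winner mode is available). An input is
highlighted unless its margin strictly exceeds θ_A (boundary ⇒ selected).
On selection, every neuron's ϑ0, m_f and h switch in place — state is
preserved, which produces the characteristic brief accuracy dip before the
higher-precision code settles — and simulation continues to T_ext = 1000 ms.

θ_A is calibrated on the training set: the smallest threshold that selects
at least 95% (a package choice; any fraction can be passed) of the inputs
misclassified at low precision, reported together with the achieved
selectivity. With a single decision time the schedule degenerates to a
constant, so calibration returns p1 = 0, p2 = θ_A; a nonzero p1 matters
only when the decision time itself is varied. If no training input is
misclassified, arousal is disabled (θ_A = −∞, selectivity 0) — on easy
tasks the low-precision network is simply trusted.

## Synthetic data and trainer

`make_blobs` draws K Gaussian clusters (unit within-cluster SD) with
centers rescaled so their minimum pairwise distance equals `separation`
(default 6 SD — a cleanly separable task, matching the regime where a
converted classifier should reproduce its analog counterpart; use 2–3 for
genuinely noisy tasks). Splits are stratified, 25% test, deterministic per
seed. The trainer is plain mini-batch gradient descent (lr 0.2, batch 32,
200 epochs) with categorical cross-entropy, He-style init, and batch
normalization trained on batch statistics then frozen to full-training-set
statistics, so the exported network is a deterministic function of the
seed. This emulates the training conditions of interest (saturating
activation + BN + cross-entropy) but none of the nuisance structure of
real data — correlated features, label noise, class imbalance,
covariate shift — so passing tests demonstrate the correctness of the
coding/conversion machinery, not robustness of the method on real
benchmarks.

## Known limitations

* dt = 1 ms caps the rate at 1000 Hz and dominates the residual oracle
  error at high rates (e.g. τ_η = 25 ms with S near 2); the simulator is
  time-stepped, not event-driven.
* SOP counting for convolutional layers uses the uniform kernel fan-out
  (border effects ignored); dense layers count exact synapses.
* The trainer covers dense + BN networks; convolutional/pooling networks
  are converted and simulated but enter via the on-disk container.
* Pooling directly before the readout is not supported (pooling merges into
  a spiking layer).
* The stochastic-spiking variant of the neuron and analog-spike-height
  (ReLU-equivalent) communication are out of scope.
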