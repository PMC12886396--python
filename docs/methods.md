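# Methods

This note documents the model implemented by `agmp`, the choices made
where the design was genuinely open, what the synthetic benchmark does
and does not probe, and the numerical conventions that matter for
reproducing its behaviour.

## Model

### Fast dynamics

Hidden layers are discrete-time leaky integrate-and-fire (LIF) neurons,
optionally with an adaptive threshold (ALIF). With leak
`alpha = exp(-dt/tau_m)` and `dt = 1` step:

    u_i[t+1]     = alpha * u_i[t] + sum_j w_ij x_j[t] + b_i - theta_i[t] * s_i[t]
    s_i[t]       = H(u_i[t] - theta_i[t])        (H(0) = 1)
    theta_i[t+1] = theta0 + rho * (theta_i[t] - theta0) + beta * s_i[t]

Spiking uses a *soft reset* (threshold subtraction), preserving
supra-threshold excess; the membrane is unbounded below. `beta = 0`
reduces ALIF to LIF exactly. Within one simulation step spikes cascade
through the whole stack (layer `l` sees layer `l-1`'s spikes of the same
step), so a deep network is still strictly causal step to step. Initial
conditions are neutral: `u = 0`, `theta = theta0`, zero spikes and rate
estimates. The bias `b_i` is injected at every step.

The readout is a non-spiking leaky integrator (same leak, no threshold,
no reset) whose per-step softmax is the class probability vector
`y[t]`; classification takes the argmax of the time-averaged `y`
(ties break to the lowest index). A leaky readout is the standard
companion of trace-based rules and keeps every layer's state O(1).

### Learning rule

The weight update is four-factor, applied at every time step with the
one-hot target held fixed over a sample (streaming supervision):

    dw_ij[t] = eta * g_i[t] * M_i[t] * e_ij[t] - eta_decay * w_ij[t]

* **Eligibility trace** (`tau_e`, default tied to `tau_m`):
  `e_ij[t+1] = lambda_e e_ij[t] + psi_i[t] x_j[t]`, with the triangular
  surrogate `psi = gamma max(0, 1 - |u - theta| / width)` evaluated at
  the pre-reset membrane that generated the current spikes. The readout
  uses `psi = 1` (identity activation), which makes its accumulated
  update *exactly* the unrolled gradient of the summed per-step
  cross-entropy when `lambda_e` equals the readout leak (a
  summation-by-parts identity; asserted in the test suite). Recurrent
  synapses use the identical recursion with the layer's own
  previous-step spikes as the presynaptic factor.
* **Learning signal**: the output error `delta[t] = y[t] - target` is
  projected to hidden layers through fixed random feedback matrices
  `B` (entry std `1/sqrt(n_out)`, zero-mean Gaussian by default, drawn
  once per layer and immutable). The modulator actually applied is the
  descent direction `M = B(-delta)` (readout: `-delta`): the
  product-of-factors form is antisymmetric in the sign of `M`, and only
  this orientation reduces the error.
* **Astrocytic gate**: each neuron integrates a nonnegative activity
  load `phi_i = eta_u |u_i| + eta_s sum_j |w_ij| x_j + eta_o s_i` on a
  slow timescale, `a_i[t+1] = lambda_a a_i[t] + (1 - lambda_a) phi_i[t]`
  with `lambda_a = exp(-1/tau_a)`, normalises it against layer-wise
  exponential running statistics,
  `a_hat = (a - mu)/(sqrt(var) + eps)`, and gates plasticity with
  `g = sigmoid(k_g a_hat + beta_g)`, shared by all synapses afferent to
  the neuron.
* **Homeostasis**: `b_i <- b_i - eta_b (r_i - r_target)` with `r_i` an
  EMA of the neuron's spikes (momentum 0.99). Applied to spiking layers
  only — a non-spiking readout has no firing rate and the rule would
  have no fixed point there.

### Gate orientation

With layer-relative normalisation, the two possible gate orientations
behave very differently on sequential tasks, and we verified both:

* `g` increasing in `a_hat` (the implemented default): neurons engaged
  by the *current* inputs stay plastic; neurons that have gone quiet —
  readout units of classes absent from the current task, hidden units
  tuned to earlier prototypes — decay below the layer mean over
  `tau_a` steps and have their afferent weights protected. On the
  synthetic split protocol this reduces forgetting relative to the
  ungated rule.
* the inverted (suppress-the-active) orientation protects exactly the
  wrong population during a task switch — the new task's units — while
  re-exposing old units once their slow state decays below the layer
  mean; empirically it *increases* forgetting here. It remains
  available via `invert_gate: true`.

### Memory complexity

All learning state (traces, astrocyte states, running statistics) is
updated recursively; the resident scalar count is a function of the
architecture only, never of elapsed time (`AGMPNetwork.state_census`
asserts this). The bundled `UnrolledBPTT` oracle is the contrast case:
it stores the full trajectory, O(T) scalars, and supplies the exact
surrogate gradient for alignment diagnostics on small instances.

## Continual protocol and metrics

Tasks are trained strictly sequentially with a single readout head over
all classes (class-incremental). Fast states reset at sample
boundaries; astrocyte states, running statistics, and rate estimates
persist across samples *and* tasks — the slow timescale spanning the
stream is the stabilisation mechanism. Running statistics are frozen
during accuracy evaluation (evaluation performs no learning-side
updates at all).

After each task `k` every seen task `j <= k` is evaluated, filling the
lower triangle of `acc[k, j]`. Average accuracy is the mean of the
final row. Forgetting is the mean over non-final tasks of the drop from
the task's best earlier accuracy to its final accuracy, floored at zero
per task (so it is zero when no task ever declines and nonnegative
otherwise; backward transfer is not netted against forgetting).
Energy proxies: `spike_count` totals presynaptic spike events during
evaluation and `synops` charges each such event one operation per
efferent synapse (spike x fan-out); counting covers evaluation passes
(inference energy), not training.

## Synthetic benchmark

Each class is a fixed random prototype of `ceil(0.2 * 100)` input
neurons firing at 0.5 per step against a 0.05 background, 50 steps per
sample, 2% per-sample membership jitter; 10 classes split contiguously
into 5 two-class tasks, 250 train / 50 test samples per class.
Prototype layout and per-sample noise come from separate seed streams
so multi-seed experiments vary only noise and initial weights. These
rate-coded patterns exercise the learning rule — credit assignment
through spiking layers, stability across distribution shifts — but not
event-camera statistics, precise-timing codes, or natural-image
structure; results here demonstrate the mechanism, and are not claimed
to predict absolute accuracies on neuromorphic benchmark datasets.

Default problem sizes for the sequential-protocol experiments (also
used by the acceptance script): 200 training samples per task, with
the full 250 per class available for stationary single-task runs. A
single task is learnable to >90% accuracy within 500 samples at the
default learning rate (`eta = 0.05`); five sequential tasks take a few
seconds per seed on one CPU core.

### Temporal-credit probe (delayed supervision)

The default stream is stationary within a sample and highly separable,
so even the instantaneous (`no_trace`) rule reaches ceiling accuracy on
it: a single step's spikes identify the class, and streaming
supervision provides thousands of updates. To measure what the
eligibility trace actually contributes — bridging the gap between the
inputs that drove a decision and the arrival of the teaching signal —
the test suite uses a *delayed-supervision* probe: a low-contrast task
(`rate_high = 0.2`, `rate_low = 0.1`) supervised only at the final step
of each 50-step sample (`train_sequence(..., supervise_from=T-1)`;
earlier steps run forward-only, traces and slow states still evolve).
There a single step's evidence is insufficient, the trace integrates
the whole sample into each update, and removing it collapses accuracy
(~80% vs ~99% for gate removal at 100 training samples). Supervision
timing is an ordinary protocol knob (`supervise_from`, default 0 =
streaming).

### Timescale protocol

The timescale sweep is a 2-D grid over `(tau_e, tau_a)` pairs, matching
the structure of the gating model (both timescales are free). The
package's separation comparison takes `tau in {20, 2000}` on each axis
and compares median forgetting at ratio `tau_a/tau_e = 100` against the
ratio-1 cells (both-fast and both-slow) over 5 seeds. On this shallow
protocol the direction holds but the margin is small: class absence
during later tasks is itself a persistent signal, so even a fast
astrocyte protects quiescent readout units, and most of the gate's
benefit survives at ratio 1 (see the `fast_astro` entries the
acceptance script reports). The separation regime matters more the
faster the within-task activity fluctuates relative to task duration.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `tau_m` | 20 steps | standard LIF memory for 50-step samples |
| `theta0`, `rho`, `beta` | 1.0, 0.95, 0 | unit threshold; ALIF opt-in |
| `gamma`, `width` | 0.3, 1.0 | conventional triangular surrogate |
| `tau_e` | `tau_m` | trace decay tied to the membrane leak (and making the readout update exact) |
| `tau_a` | 2000 steps | 100x the eligibility timescale, inside the 50-500x separation regime; ~40 samples of memory |
| `eta_u, eta_s, eta_o` | 0.1, 0.1, 1.0 | spikes dominate the load; membrane/input terms keep non-spiking activity visible |
| `k_g`, `beta_g`, `eps` | 1.0, 0.0, 1e-6 | unbiased sigmoid, unit slope |
| `stats_momentum` | 0.99 | ~100-step statistics window, well under `tau_a` |
| `eta` | 0.05 | fast single-task acquisition without divergence |
| `eta_b`, `r_target` | 1e-3, 0.1 | gentle drift toward sparse (10%) firing |

## Numerical conventions and edge cases

* Heaviside boundary fires: `u == theta` emits a spike (deterministic).
* The gate is clipped to `[1e-12, 1 - 1e-12]` because the sigmoid
  saturates to exactly 0/1 in float64 beyond |z| ~ 37; the gate is
  strictly inside the unit interval by contract.
* Degenerate layer statistics (`var = 0`, e.g. at cold start) give
  `a_hat = 0` up to the `eps` floor, i.e. a uniform gate
  `sigmoid(beta_g)`.
* All state is IEEE-754 double; checkpoints (HDF5) restore training
  bit-exactly, including running statistics and the feedback matrices
  (stored with their seeds).
* Fixed seeds make every run bit-reproducible; the generator and the
  network consume independent seed streams derived via `SeedSequence`.

## Known limitations

* The eligibility trace is the LIF-derived recursion for ALIF layers
  too; the richer adaptation-coupled trace from the eligibility-
  propagation literature is not implemented.
* Feedback is random and fixed; no feedback learning or weight
  transport. Hidden-layer credit is approximate (positive gradient
  alignment, not equality).
* Single-sample streaming only (no mini-batching); dense layers only
  (no convolutional weight sharing); one recurrent layer at most.
* The forgetting comparisons are directional claims on the synthetic
  protocol, not reproductions of any published benchmark numbers.
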