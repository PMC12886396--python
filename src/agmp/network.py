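"""Deep spiking network with the strictly online four-factor learning loop.

A network is a stack of LIF/ALIF layers (optionally one recurrent layer)
followed by a non-spiking leaky-integrator readout whose per-step softmax
gives the class probabilities ``y[t]``.  Every quantity needed for
learning — eligibility traces, astrocyte states, layer running
statistics — is updated recursively, so the resident state is a function
of the architecture (N neurons, S synapses) only, never of the elapsed
number of steps: the O(1)-in-time memory contract.  ``state_census``
counts the stored scalars so that contract can be asserted.

Per training step (one pass of the online loop):

1. forward cascade: spikes propagate through all layers, readout
   integrates and emits ``y[t]``;
2. per layer: surrogate pseudo-derivative -> eligibility-trace update;
3. per layer: activity-load drive -> slow astrocyte update -> running
   stats -> gate;
4. output error ``delta = y - y_target``; hidden layers receive the
   broadcast ``B @ delta`` through fixed random feedback matrices;
5. four-factor weight update and homeostatic bias update.

Sign convention: the modulatory factor applied in the update is the
*descent* signal ``-delta`` (resp. ``B @ -delta``), so each update moves
the readout probabilities toward the target.

Ablation variants: ``no_gate`` clamps the gate to 1, ``no_trace``
replaces the fading trace by the instantaneous product ``psi x``, and
``no_homeostasis`` freezes the bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import h5py
from scipy.special import softmax

from .neurons import NeuronParams, LayerState, step_membrane, update_rate
from .plasticity import (
    SurrogateParams,
    EligibilityState,
    BroadcastMatrix,
    surrogate_derivative,
    update_trace,
    output_error,
    broadcast,
)
from .astrocyte import (
    AstrocyteParams,
    AstrocyteState,
    PlasticityConfig,
    drive,
    update_astrocyte,
    update_stats,
    gate,
    weight_update,
    homeostatic_bias,
)

__all__ = ["NetworkSpec", "AGMPNetwork", "VARIANTS"]

VARIANTS = ("full", "no_gate", "no_trace", "no_homeostasis")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: sizes [n_in, n_1, ..., n_L], per-layer kinds, seed.

    The final layer kind must be ``"readout"`` (non-spiking leaky
    integrator); hidden kinds are ``"lif"`` or ``"alif"``.  ``recurrent``
    flags add a same-layer recurrent weight matrix (hidden layers only).
    The master seed governs weight initialisation and the feedback
    matrices.
    """

    layer_sizes: tuple[int, ...]
    layer_kinds: tuple[str, ...]
    recurrent: tuple[bool, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least an input and a readout layer")
        if any(n <= 0 for n in self.layer_sizes):
            raise ValueError(f"nonpositive layer size in {self.layer_sizes}")
        if len(self.layer_kinds) != len(self.layer_sizes) - 1:
            raise ValueError("layer_kinds must have one entry per non-input layer")
        if len(self.recurrent) != len(self.layer_kinds):
            raise ValueError("recurrent must have one entry per non-input layer")
        for k in self.layer_kinds[:-1]:
            if k not in ("lif", "alif"):
                raise ValueError(f"hidden layer kind must be lif|alif, got {k!r}")
        if self.layer_kinds[-1] != "readout":
            raise ValueError("last layer kind must be 'readout'")
        if self.recurrent[-1]:
            raise ValueError("the readout layer cannot be recurrent")

    @classmethod
    def feedforward(
        cls,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        kind: str = "lif",
        recurrent: bool = False,
        seed: int = 0,
    ) -> "NetworkSpec":
        """Convenience builder for a plain stack (recurrence, if any, on
        the last hidden layer)."""
        n_hid = len(hidden)
        rec = tuple(recurrent and i == n_hid - 1 for i in range(n_hid)) + (False,)
        return cls(
            layer_sizes=(n_in, *hidden, n_out),
            layer_kinds=(kind,) * n_hid + ("readout",),
            recurrent=rec,
            seed=seed,
        )

    @property
    def n_in(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_out(self) -> int:
        return self.layer_sizes[-1]


@dataclass
class _Layer:
    """Internal per-layer bundle of parameters and state."""

    kind: str
    W: np.ndarray
    b: np.ndarray
    state: LayerState
    elig: EligibilityState
    astro: AstrocyteState
    B: BroadcastMatrix | None  # None for the readout layer
    W_rec: np.ndarray | None = None
    elig_rec: EligibilityState | None = None
    dW_accum: np.ndarray | None = None
    dW_rec_accum: np.ndarray | None = None

    @property
    def is_readout(self) -> bool:
        return self.kind == "readout"

    @property
    def n(self) -> int:
        return self.W.shape[0]


class AGMPNetwork:
    """Online-trainable spiking classifier.

    Parameters
    ----------
    spec:
        Architecture and master seed.
    neuron, surrogate, astro, plast:
        Parameter bundles for the dynamics and plasticity; defaults are
        the package defaults of each dataclass.
    tau_e:
        Eligibility time constant (steps).  Defaults to the membrane
        time constant, tying ``lambda_e`` to the membrane leak.
    rate_momentum:
        Momentum of the firing-rate EMA feeding the homeostatic rule.
    variant:
        One of ``full | no_gate | no_trace | no_homeostasis``.
    reset_fast_between_samples:
        Zero membranes, thresholds, spikes and traces at sample
        boundaries (default True).
    persist_astrocyte, persist_rate:
        Whether the slow states survive sample boundaries (default True;
        the slow timescale spanning the whole stream is the
        continual-learning mechanism).
    gate_readout:
        Apply the astrocytic gate to the readout layer too (default
        True); the readout is never homeostated (it has no spikes).
    accumulate_updates:
        If True, weight updates are accumulated in per-layer buffers
        instead of applied; call :meth:`apply_accumulated` at a sequence
        boundary (or read the buffers directly, e.g. for gradient
        diagnostics).
    """

    def __init__(
        self,
        spec: NetworkSpec,
        *,
        neuron: NeuronParams | None = None,
        surrogate: SurrogateParams | None = None,
        astro: AstrocyteParams | None = None,
        plast: PlasticityConfig | None = None,
        tau_e: float | None = None,
        rate_momentum: float = 0.99,
        variant: str = "full",
        reset_fast_between_samples: bool = True,
        persist_astrocyte: bool = True,
        persist_rate: bool = True,
        gate_readout: bool = True,
        accumulate_updates: bool = False,
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
        self.spec = spec
        self.neuron = neuron or NeuronParams()
        self.surrogate = surrogate or SurrogateParams()
        self.astro = astro or AstrocyteParams()
        self.plast = plast or PlasticityConfig()
        self.tau_e = float(tau_e) if tau_e is not None else self.neuron.tau_m
        self.rate_momentum = rate_momentum
        self.variant = variant
        self.reset_fast_between_samples = reset_fast_between_samples
        self.persist_astrocyte = persist_astrocyte
        self.persist_rate = persist_rate
        self.gate_readout = gate_readout
        self.accumulate_updates = accumulate_updates

        self.step_counter = 0
        self.synops = 0.0
        self.spike_count = 0.0
        self.count_ops = False
        self._op_log: list | None = None
        self._build()

    # ------------------------------------------------------------------ init

    def _build(self) -> None:
        ss = np.random.SeedSequence(self.spec.seed)
        # one uint32-derived child seed per layer for W, plus one per
        # hidden layer for B and one per recurrent matrix; all < 2**31
        raw = ss.generate_state(4 * len(self.spec.layer_kinds)).astype(np.int64)
        seeds = (raw & 0x7FFFFFFF).tolist()
        self.layers: list[_Layer] = []
        sizes = self.spec.layer_sizes
        n_out = self.spec.n_out
        for i, kind in enumerate(self.spec.layer_kinds):
            n_pre, n_post = sizes[i], sizes[i + 1]
            rng = np.random.default_rng(seeds[4 * i])
            W = rng.normal(0.0, 1.0 / np.sqrt(n_pre), size=(n_post, n_pre))
            state = LayerState.zeros(n_post, self.neuron)
            if kind == "readout":
                # non-spiking leaky integrator: theta/s unused, keep zeros
                state.theta = np.zeros(n_post)
                state.s = np.zeros(n_post)
                Bmat = None
            else:
                Bmat = BroadcastMatrix.create(n_post, n_out, seed=seeds[4 * i + 1])
            W_rec = None
            elig_rec = None
            if self.spec.recurrent[i]:
                rng_rec = np.random.default_rng(seeds[4 * i + 2])
                W_rec = rng_rec.normal(0.0, 1.0 / np.sqrt(n_post), size=(n_post, n_post))
                elig_rec = EligibilityState.zeros(n_post, n_post, self.tau_e)
            self.layers.append(
                _Layer(
                    kind=kind,
                    W=W,
                    b=np.zeros(n_post),
                    state=state,
                    elig=EligibilityState.zeros(n_post, n_pre, self.tau_e),
                    astro=AstrocyteState.zeros(n_post),
                    B=Bmat,
                    W_rec=W_rec,
                    elig_rec=elig_rec,
                )
            )
        self.reset_accumulators()

    def reset_accumulators(self) -> None:
        for layer in self.layers:
            layer.dW_accum = np.zeros_like(layer.W)
            if layer.W_rec is not None:
                layer.dW_rec_accum = np.zeros_like(layer.W_rec)

    def reset_fast(self) -> None:
        """Reset the fast states (membranes, thresholds, spikes, traces)
        at a sample boundary; slow states persist per configuration."""
        for layer in self.layers:
            r = layer.state.r
            layer.state = LayerState.zeros(layer.n, self.neuron)
            if layer.is_readout:
                layer.state.theta = np.zeros(layer.n)
                layer.state.s = np.zeros(layer.n)
            if self.persist_rate:
                layer.state.r = r
            layer.elig = EligibilityState.zeros(*layer.elig.e.shape, self.tau_e)
            if layer.elig_rec is not None:
                layer.elig_rec = EligibilityState.zeros(layer.n, layer.n, self.tau_e)
            if not self.persist_astrocyte:
                layer.astro = AstrocyteState.zeros(layer.n)

    # --------------------------------------------------------------- forward

    def forward_step(self, x_t: np.ndarray, _collect: bool = False):
        """Propagate one input-spike vector through all layers.

        Returns the readout probability vector ``y[t]`` (softmax of the
        readout membrane).  Spikes cascade through the stack within the
        step: layer l sees layer l-1's spikes of this same step, so no
        state indexed by time is ever stored.
        """
        x_t = np.asarray(x_t, dtype=float)
        if x_t.shape != (self.spec.n_in,):
            raise ValueError(
                f"input length {x_t.shape} does not match n_in={self.spec.n_in}"
            )
        records = [] if _collect else None
        cur = x_t
        y = None
        for layer in self.layers:
            pre = cur
            pre_rec = None
            if self.count_ops:
                n_spk = float(pre.sum())
                self.synops += n_spk * layer.n
                self.spike_count += n_spk
                if layer.W_rec is not None:
                    self.synops += float(layer.state.s.sum()) * layer.n
                if self._op_log is not None:
                    self._op_log.append((pre.copy(), layer.n, None if layer.W_rec is None else layer.state.s.copy()))
            if layer.is_readout:
                layer.state.u = (
                    self.neuron.alpha * layer.state.u + layer.W @ pre + layer.b
                )
                y = softmax(layer.state.u)
            else:
                presyn = layer.W @ pre
                if layer.W_rec is not None:
                    pre_rec = layer.state.s.copy()
                    presyn = presyn + layer.W_rec @ pre_rec
                new_state = step_membrane(layer.state, self.neuron, presyn, layer.b)
                new_state.r = update_rate(new_state, self.rate_momentum)
                layer.state = new_state
                cur = new_state.s
            if _collect:
                records.append((pre, pre_rec))
        self.step_counter += 1
        return (y, records) if _collect else y

    # -------------------------------------------------------------- training

    def online_train_step(
        self, x_t: np.ndarray, y_target: np.ndarray, learn: bool = True
    ) -> dict[str, object]:
        """One pass of the online loop; returns per-layer diagnostics.

        With ``learn=False`` the traces, astrocyte states and gates
        still evolve but no weight or bias update is applied (used for
        the pre-supervision portion of delayed-teaching protocols).
        """
        y, records = self.forward_step(x_t, _collect=True)
        delta = output_error(y, y_target)
        err = -delta  # descent modulator: push y toward the target
        diag: dict[str, object] = {"y": y, "layers": []}
        for layer, (pre, pre_rec) in zip(self.layers, records):
            if layer.is_readout:
                # identity "activation": pseudo-derivative 1 everywhere
                psi = np.ones(layer.n)
            else:
                psi = surrogate_derivative(layer.state.u, layer.state.theta, self.surrogate)

            if self.variant == "no_trace":
                e_used = np.outer(psi, pre)
                e_rec_used = None if pre_rec is None else np.outer(psi, pre_rec)
            else:
                layer.elig = update_trace(layer.elig, psi, pre)
                e_used = layer.elig.e
                e_rec_used = None
                if pre_rec is not None:
                    layer.elig_rec = update_trace(layer.elig_rec, psi, pre_rec)
                    e_rec_used = layer.elig_rec.e

            phi = drive(layer.state.u, layer.W, pre, layer.state.s, self.astro)
            layer.astro.a = update_astrocyte(layer.astro.a, phi, self.astro)
            update_stats(layer.astro, self.astro)
            if self.variant == "no_gate" or (layer.is_readout and not self.gate_readout):
                g = np.ones(layer.n)
            else:
                g = gate(layer.astro, self.astro)
            layer.astro.g = g

            M = err if layer.is_readout else broadcast(layer.B, err)

            diag_dw = 0.0
            if not learn:
                pass
            elif self.accumulate_updates:
                layer.dW_accum += (self.plast.eta * (g * M))[:, None] * e_used
                if e_rec_used is not None:
                    layer.dW_rec_accum += (self.plast.eta * (g * M))[:, None] * e_rec_used
            else:
                W_before = layer.W
                layer.W = weight_update(layer.W, g, M, e_used, self.plast)
                diag_dw = float(np.abs(layer.W - W_before).mean())
                if e_rec_used is not None:
                    layer.W_rec = weight_update(layer.W_rec, g, M, e_rec_used, self.plast)

            if (
                learn
                and not layer.is_readout
                and self.variant != "no_homeostasis"
                and self.plast.eta_b > 0
            ):
                layer.b = homeostatic_bias(layer.b, layer.state.r, self.plast)

            diag["layers"].append(
                {
                    "mean_gate": float(np.mean(g)),
                    "mean_abs_dw": diag_dw,
                    "spike_count": float(layer.state.s.sum()),
                }
            )
        return diag

    def apply_accumulated(self) -> None:
        """Apply and clear the per-sequence accumulated updates."""
        for layer in self.layers:
            layer.W = layer.W + layer.dW_accum - self.plast.eta_decay * layer.W
            if layer.W_rec is not None:
                layer.W_rec = (
                    layer.W_rec + layer.dW_rec_accum - self.plast.eta_decay * layer.W_rec
                )
        self.reset_accumulators()

    def train_sequence(
        self,
        sample: np.ndarray,
        label: int,
        n_classes: int | None = None,
        supervise_from: int = 0,
    ) -> dict[str, float]:
        """Train on one spike tensor [T, n_in] with streaming supervision.

        The one-hot target is applied at every step from
        ``supervise_from`` onward (default 0: every step).  A late
        supervision window is the classic delayed-teaching protocol:
        the eligibility trace must bridge the gap between the inputs
        that drove the decision and the arrival of the teaching signal.
        Before the window opens, the step runs forward-only (states and
        traces evolve, no weight or bias updates).

        Fast states reset at the sample boundary (configurable);
        astrocyte states and firing-rate estimates persist.  Returns
        diagnostics including the cross-entropy of the time-averaged
        readout.
        """
        sample = np.asarray(sample, dtype=float)
        if sample.ndim != 2 or sample.shape[1] != self.spec.n_in:
            raise ValueError(f"sample must be [T, {self.spec.n_in}], got {sample.shape}")
        n_classes = n_classes or self.spec.n_out
        target = np.zeros(n_classes)
        target[label] = 1.0
        if self.reset_fast_between_samples:
            self.reset_fast()
        y_sum = np.zeros(self.spec.n_out)
        gate_sum = 0.0
        for t, x_t in enumerate(sample):
            diag = self.online_train_step(x_t, target, learn=(t >= supervise_from))
            y_sum += diag["y"]
            gate_sum += float(np.mean([d["mean_gate"] for d in diag["layers"]]))
        T = sample.shape[0]
        y_bar = y_sum / T
        loss = -float(np.log(max(y_bar[label], 1e-300)))
        return {"loss": loss, "mean_gate": gate_sum / T, "y_bar": y_bar}

    # ------------------------------------------------------------- inference

    def predict(self, sample: np.ndarray) -> int:
        """Label by argmax of the time-averaged readout probabilities.

        Weights, astrocyte states and running statistics are untouched
        (statistics are frozen during evaluation); fast states are reset
        before and after.  Ties break toward the lowest index.
        """
        probs = self.predict_proba(sample)
        return int(np.argmax(probs))

    def predict_proba(self, sample: np.ndarray) -> np.ndarray:
        sample = np.asarray(sample, dtype=float)
        self.reset_fast()
        y_sum = np.zeros(self.spec.n_out)
        for x_t in sample:
            y_sum += self.forward_step(x_t)
        self.reset_fast()
        return y_sum / sample.shape[0]

    def evaluate(
        self, X: np.ndarray, labels: np.ndarray, count_ops: bool = False
    ) -> float:
        """Accuracy over a labelled set of spike tensors [n, T, n_in]."""
        prev = self.count_ops
        self.count_ops = count_ops
        try:
            correct = sum(self.predict(x) == int(t) for x, t in zip(X, labels))
        finally:
            self.count_ops = prev
        return correct / len(labels)

    # ----------------------------------------------------------- bookkeeping

    def state_census(self) -> int:
        """Number of resident state scalars.

        A function of the architecture only — asserting equality of this
        count across runs of different lengths is the O(1) temporal
        memory check.
        """
        n = 1  # step counter
        for layer in self.layers:
            n += layer.W.size + layer.b.size
            n += sum(v.size for v in layer.state.to_dict().values())
            n += layer.elig.e.size
            n += layer.astro.a.size + 2  # mu, var
            n += layer.astro.g.size if layer.astro.g is not None else 0
            if layer.B is not None:
                n += layer.B.B.size
            if layer.W_rec is not None:
                n += layer.W_rec.size + layer.elig_rec.e.size
        return n

    def _config_dict(self) -> dict:
        return {
            "spec": {
                "layer_sizes": list(self.spec.layer_sizes),
                "layer_kinds": list(self.spec.layer_kinds),
                "recurrent": list(self.spec.recurrent),
                "seed": self.spec.seed,
            },
            "neuron": asdict(self.neuron),
            "surrogate": asdict(self.surrogate),
            "astro": asdict(self.astro),
            "plast": asdict(self.plast),
            "tau_e": self.tau_e,
            "rate_momentum": self.rate_momentum,
            "variant": self.variant,
            "reset_fast_between_samples": self.reset_fast_between_samples,
            "persist_astrocyte": self.persist_astrocyte,
            "persist_rate": self.persist_rate,
            "gate_readout": self.gate_readout,
            "accumulate_updates": self.accumulate_updates,
        }

    def save(self, path: str) -> None:
        """Checkpoint everything needed to continue training bit-exactly."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(self._config_dict())
            f.attrs["step_counter"] = self.step_counter
            f.attrs["synops"] = self.synops
            f.attrs["spike_count"] = self.spike_count
            for i, layer in enumerate(self.layers):
                grp = f.create_group(f"layer_{i}")
                grp.create_dataset("W", data=layer.W)
                grp.create_dataset("b", data=layer.b)
                for k, v in layer.state.to_dict().items():
                    grp.create_dataset(k, data=v)
                grp.create_dataset("e", data=layer.elig.e)
                grp.create_dataset("a", data=layer.astro.a)
                if layer.astro.g is not None:
                    grp.create_dataset("g", data=layer.astro.g)
                grp.attrs["mu"] = layer.astro.mu
                grp.attrs["var"] = layer.astro.var
                if layer.B is not None:
                    grp.create_dataset("B", data=layer.B.B)
                    grp.attrs["B_seed"] = layer.B.seed
                if layer.W_rec is not None:
                    grp.create_dataset("W_rec", data=layer.W_rec)
                    grp.create_dataset("e_rec", data=layer.elig_rec.e)

    @classmethod
    def load(cls, path: str) -> "AGMPNetwork":
        with h5py.File(path, "r") as f:
            cfg = json.loads(f.attrs["config"])
            spec = NetworkSpec(
                layer_sizes=tuple(cfg["spec"]["layer_sizes"]),
                layer_kinds=tuple(cfg["spec"]["layer_kinds"]),
                recurrent=tuple(cfg["spec"]["recurrent"]),
                seed=cfg["spec"]["seed"],
            )
            net = cls(
                spec,
                neuron=NeuronParams(**cfg["neuron"]),
                surrogate=SurrogateParams(**cfg["surrogate"]),
                astro=AstrocyteParams(**cfg["astro"]),
                plast=PlasticityConfig(**cfg["plast"]),
                tau_e=cfg["tau_e"],
                rate_momentum=cfg["rate_momentum"],
                variant=cfg["variant"],
                reset_fast_between_samples=cfg["reset_fast_between_samples"],
                persist_astrocyte=cfg["persist_astrocyte"],
                persist_rate=cfg["persist_rate"],
                gate_readout=cfg["gate_readout"],
                accumulate_updates=cfg["accumulate_updates"],
            )
            net.step_counter = int(f.attrs["step_counter"])
            net.synops = float(f.attrs["synops"])
            net.spike_count = float(f.attrs["spike_count"])
            for i, layer in enumerate(net.layers):
                grp = f[f"layer_{i}"]
                layer.W = grp["W"][()]
                layer.b = grp["b"][()]
                layer.state = LayerState.from_dict({k: grp[k][()] for k in ("u", "theta", "s", "r")})
                layer.elig = EligibilityState(grp["e"][()], layer.elig.lambda_e)
                layer.astro = AstrocyteState(
                    a=grp["a"][()],
                    mu=float(grp.attrs["mu"]),
                    var=float(grp.attrs["var"]),
                    g=grp["g"][()] if "g" in grp else None,
                )
                if "B" in grp:
                    layer.B = BroadcastMatrix(B=grp["B"][()].copy(), seed=int(grp.attrs["B_seed"]))
                if "W_rec" in grp:
                    layer.W_rec = grp["W_rec"][()]
                    layer.elig_rec = EligibilityState(grp["e_rec"][()], layer.elig.lambda_e)
        return net
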