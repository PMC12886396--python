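"""Unrolled backpropagation-through-time (BPTT) reference oracle.

A deliberately naive, history-storing implementation used only for
diagnostics and tests:

* it computes the *exact* surrogate gradient of the summed per-step
  cross-entropy for a 1-hidden-layer LIF network with a leaky softmax
  readout, by storing the full forward trajectory and unrolling the
  backward pass — the thing the online rule is designed to avoid;
* its resident storage grows linearly with the sequence length ``T``
  (``storage_scalars`` counts it), the contrast class for the O(1)
  temporal-memory check;
* :func:`alignment_experiment` measures the cosine similarity between
  the accumulated online (gate-clamped) update and this exact gradient's
  descent direction on a small random instance.

The forward pass replicates the network module's conventions exactly:
spikes cascade through the stack within a step, soft reset subtracts the
threshold, and the spike at ``t`` is generated from the pre-reset
membrane at ``t``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .neurons import NeuronParams
from .plasticity import SurrogateParams
from .astrocyte import PlasticityConfig
from .network import NetworkSpec, AGMPNetwork

__all__ = ["UnrolledBPTT", "alignment_experiment"]


class UnrolledBPTT:
    """Exact surrogate-BPTT gradients for n_in -> n_hidden(LIF) -> readout.

    Loss: ``L = sum_t CE(softmax(u_out[t]), target)`` over the steps of
    one sample, matching the online rule's streaming supervision.
    """

    def __init__(
        self,
        W_h: np.ndarray,
        b_h: np.ndarray,
        W_o: np.ndarray,
        b_o: np.ndarray,
        neuron: NeuronParams,
        surrogate: SurrogateParams,
    ) -> None:
        self.W_h = W_h
        self.b_h = b_h
        self.W_o = W_o
        self.b_o = b_o
        self.neuron = neuron
        self.surrogate = surrogate
        self._history_scalars = 0

    def run(self, sample: np.ndarray, target: np.ndarray) -> dict:
        """Forward with stored history, then unrolled backward.

        Returns gradients of the summed per-step cross-entropy w.r.t.
        both weight matrices, plus the stored trajectories.
        """
        p = self.neuron
        sp = self.surrogate
        alpha = p.alpha
        T, n_in = sample.shape
        n_h = self.W_h.shape[0]
        n_o = self.W_o.shape[0]
        theta = p.theta0  # LIF only: constant threshold

        # ---- forward, storing everything (the O(T) history) ----
        u_h = np.zeros((T + 1, n_h))
        s_h = np.zeros((T + 1, n_h))
        u_o = np.zeros((T + 1, n_o))
        y = np.zeros((T + 1, n_o))
        for t in range(T):
            u_h[t + 1] = alpha * u_h[t] + self.W_h @ sample[t] + self.b_h - theta * s_h[t]
            s_h[t + 1] = (u_h[t + 1] >= theta).astype(float)
            u_o[t + 1] = alpha * u_o[t] + self.W_o @ s_h[t + 1] + self.b_o
            y[t + 1] = softmax(u_o[t + 1])
        self._history_scalars = u_h.size + s_h.size + u_o.size + y.size

        # ---- backward ----
        gW_h = np.zeros_like(self.W_h)
        gW_o = np.zeros_like(self.W_o)
        gu_o_next = np.zeros(n_o)
        gu_h_next = np.zeros(n_h)
        for t in range(T, 0, -1):
            gu_o = (y[t] - target) + alpha * gu_o_next
            gW_o += np.outer(gu_o, s_h[t])
            # s_h[t] feeds the readout at t and the reset of u_h[t+1]
            gs_h = self.W_o.T @ gu_o - theta * gu_h_next
            psi = sp.gamma * np.maximum(0.0, 1.0 - np.abs(u_h[t] - theta) / sp.width)
            gu_h = psi * gs_h + alpha * gu_h_next
            gW_h += np.outer(gu_h, sample[t - 1])
            gu_o_next = gu_o
            gu_h_next = gu_h
        loss = -float(np.sum(np.log(np.maximum(y[1:][np.arange(T), np.argmax(target)], 1e-300))))
        return {
            "gW_h": gW_h,
            "gW_o": gW_o,
            "loss": loss,
            "u_h": u_h,
            "s_h": s_h,
            "y": y[1:],
        }

    def storage_scalars(self) -> int:
        """Scalars resident after a run — grows linearly in T."""
        return self._history_scalars


def alignment_experiment(
    seed: int,
    n_in: int = 20,
    n_hidden: int = 16,
    n_out: int = 2,
    T: int = 20,
    input_rate: float = 0.4,
) -> float:
    """Cosine similarity between the online update and exact BPTT descent.

    Builds a small random LIF network, draws one Bernoulli spike sample
    and a random target, accumulates the gate-clamped online update over
    the sequence (updates buffered, not applied, so both rules see the
    same trajectory), and compares it against ``-grad`` from the
    unrolled oracle on the concatenated weight vector.
    """
    rng = np.random.default_rng(seed)
    sample = (rng.random((T, n_in)) < input_rate).astype(float)
    label = int(rng.integers(n_out))
    target = np.zeros(n_out)
    target[label] = 1.0

    neuron = NeuronParams(tau_m=10.0, beta=0.0)
    surr = SurrogateParams()
    spec = NetworkSpec.feedforward(n_in, (n_hidden,), n_out, seed=seed)
    net = AGMPNetwork(
        spec,
        neuron=neuron,
        surrogate=surr,
        plast=PlasticityConfig(eta=1.0, eta_decay=0.0, eta_b=0.0),
        tau_e=neuron.tau_m,  # lambda_e = alpha so the readout trace matches BPTT's leak filter
        variant="no_gate",
        accumulate_updates=True,
    )
    oracle = UnrolledBPTT(
        net.layers[0].W.copy(),
        net.layers[0].b.copy(),
        net.layers[1].W.copy(),
        net.layers[1].b.copy(),
        neuron,
        surr,
    )
    res = oracle.run(sample, target)

    net.reset_fast()
    for x_t in sample:
        net.online_train_step(x_t, target)
    upd = np.concatenate(
        [net.layers[0].dW_accum.ravel(), net.layers[1].dW_accum.ravel()]
    )
    descent = -np.concatenate([res["gW_h"].ravel(), res["gW_o"].ravel()])
    nu, nd = np.linalg.norm(upd), np.linalg.norm(descent)
    if nu == 0.0 or nd == 0.0:
        return 0.0
    return float(upd @ descent / (nu * nd))
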