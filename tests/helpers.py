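"""Shared slow reference implementations used by several test modules."""

import numpy as np

from agmp.neurons import LayerState, step_membrane
from agmp.plasticity import EligibilityState, surrogate_derivative, update_trace


def run_plain_three_factor(net_like, xs, target):
    """Independent flat re-implementation of the ungated three-factor rule.

    Mirrors the online loop (forward cascade, trace update, broadcast,
    update) for a feedforward stack using only the primitive module
    operations, sharing nothing with :class:`AGMPNetwork` but the
    initial weights.  Returns the per-step weight trajectories.
    """
    neuron, surr, plast = net_like.neuron, net_like.surrogate, net_like.plast
    W = [l.W.copy() for l in net_like.layers]
    b = [l.b.copy() for l in net_like.layers]
    B = [None if l.B is None else l.B.B.copy() for l in net_like.layers]
    n_hidden = len(W) - 1
    sizes = [Wl.shape[0] for Wl in W]
    states = [LayerState.zeros(sizes[i], neuron) for i in range(n_hidden)]
    u_out = np.zeros(sizes[-1])
    elig = [
        EligibilityState.zeros(W[i].shape[0], W[i].shape[1], net_like.tau_e)
        for i in range(len(W))
    ]
    trajectory = []
    for x in xs:
        pres = [np.asarray(x, dtype=float)]
        for i in range(n_hidden):
            states[i] = step_membrane(states[i], neuron, W[i] @ pres[i], b[i])
            pres.append(states[i].s)
        u_out = neuron.alpha * u_out + W[-1] @ pres[-1] + b[-1]
        ey = np.exp(u_out - u_out.max())
        y = ey / ey.sum()
        err = -(y - target)
        for i in range(n_hidden):
            psi = surrogate_derivative(states[i].u, states[i].theta, surr)
            elig[i] = update_trace(elig[i], psi, pres[i])
            M = B[i] @ err
            W[i] = W[i] + (plast.eta * (np.ones(len(M)) * M))[:, None] * elig[i].e
        elig[-1] = update_trace(elig[-1], np.ones(sizes[-1]), pres[-1])
        W[-1] = W[-1] + (plast.eta * (np.ones(sizes[-1]) * err))[:, None] * elig[-1].e
        trajectory.append([Wl.copy() for Wl in W])
    return trajectory
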