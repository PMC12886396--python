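"""The fourth factor: slow astrocyte state, sigmoid gating, and the
four-factor weight update.

Each neuron carries a scalar astrocyte state ``a`` that integrates a
nonnegative "activity load" drive on a slow timescale ``tau_a`` (much
slower than the membrane and eligibility timescales).  The state is
normalised against layer-wise exponential moving statistics and squashed
through a sigmoid to produce a gate ``g in (0, 1)`` shared by all
synapses afferent to the neuron.  The gate multiplies the three-factor
update (learning signal x eligibility trace), acting as an
activity-driven dynamic learning rate; a small weight-decay term and a
homeostatic bias rule complete the plasticity machinery.

Gate orientation
----------------
By default the gate *increases* with the normalised astrocyte state:
neurons whose recent activity load sits above the layer average — the
ones engaged by the current input distribution — stay plastic, while
neurons that have fallen quiet (e.g. readout units of classes absent
from the current task) drop below the layer mean as their slow state
decays and have their afferent weights protected.  Because the slow
state remembers activity over ``tau_a`` steps, this selective write
permission is what retains earlier tasks while new ones are acquired.
``invert_gate=True`` flips the sign for the opposite (suppress-the-
active) reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "AstrocyteParams",
    "AstrocyteState",
    "PlasticityConfig",
    "drive",
    "update_astrocyte",
    "update_stats",
    "gate",
    "weight_update",
    "homeostatic_bias",
]


@dataclass(frozen=True)
class AstrocyteParams:
    """Parameters of the slow gating pathway.

    Parameters
    ----------
    tau_a:
        Astrocyte integration time constant in steps.  Intended to be
        much larger than the eligibility timescale (50-500x); values
        below it are allowed but defeat the timescale separation.
    eta_u, eta_s, eta_o:
        Nonnegative weights of the membrane-potential, synaptic-input,
        and output-spike terms in the activity-load drive.
    k_g:
        Gate slope (> 0).
    beta_g:
        Gate offset; negative values bias the layer toward stability.
    eps:
        Floor added to the running standard deviation in the
        normalisation denominator.
    stats_momentum:
        Momentum of the layer-wise running mean/variance of ``a``.
    invert_gate:
        If True, high normalised astrocyte state closes the gate instead
        of opening it (see module docstring); default False.
    """

    tau_a: float = 2000.0
    eta_u: float = 0.1
    eta_s: float = 0.1
    eta_o: float = 1.0
    k_g: float = 1.0
    beta_g: float = 0.0
    eps: float = 1e-6
    stats_momentum: float = 0.99
    invert_gate: bool = False

    def __post_init__(self) -> None:
        if self.tau_a <= 0:
            raise ValueError(f"tau_a must be > 0, got {self.tau_a}")
        if min(self.eta_u, self.eta_s, self.eta_o) < 0:
            raise ValueError("drive coefficients eta_u/eta_s/eta_o must be >= 0")
        if self.k_g <= 0:
            raise ValueError(f"k_g must be > 0, got {self.k_g}")
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if not (0.0 < self.stats_momentum < 1.0):
            raise ValueError(f"stats_momentum must be in (0, 1), got {self.stats_momentum}")

    @property
    def lambda_a(self) -> float:
        """Per-step decay ``exp(-1 / tau_a)`` of the astrocyte state."""
        return math.exp(-1.0 / self.tau_a)


@dataclass
class AstrocyteState:
    """Per-neuron slow state plus layer running statistics and gates."""

    a: np.ndarray
    mu: float = 0.0
    var: float = 0.0
    g: np.ndarray | None = None

    @classmethod
    def zeros(cls, n: int) -> "AstrocyteState":
        return cls(a=np.zeros(n), mu=0.0, var=0.0, g=np.full(n, 0.5))

    def copy(self) -> "AstrocyteState":
        return AstrocyteState(
            self.a.copy(), self.mu, self.var, None if self.g is None else self.g.copy()
        )


def drive(
    u: np.ndarray,
    W: np.ndarray,
    x_pre: np.ndarray,
    s: np.ndarray,
    p: AstrocyteParams,
) -> np.ndarray:
    """Nonnegative activity load of each neuron at this step.

    ``phi_i = eta_u |u_i| + eta_s sum_j |W_ij| x_j + eta_o s_i`` —
    absolute membrane deflection, rectified synaptic input load, and
    output spiking, with configurable relative weights.
    """
    u = np.asarray(u, dtype=float)
    x_pre = np.asarray(x_pre, dtype=float)
    s = np.asarray(s, dtype=float)
    if W.shape != (u.shape[0], x_pre.shape[0]) or s.shape != u.shape:
        raise ValueError("drive: incompatible shapes")
    return p.eta_u * np.abs(u) + p.eta_s * (np.abs(W) @ x_pre) + p.eta_o * s


def update_astrocyte(a: np.ndarray, phi: np.ndarray, p: AstrocyteParams) -> np.ndarray:
    """Slow leaky integration ``a' = lambda_a a + (1 - lambda_a) phi``.

    A convex combination, so ``a'`` lies elementwise between ``a`` and
    the drive; with nonnegative drive and zero initialisation ``a >= 0``
    for all time.
    """
    lam = p.lambda_a
    return lam * a + (1.0 - lam) * phi


def update_stats(state: AstrocyteState, p: AstrocyteParams) -> None:
    """Advance the layer-wise running mean/variance of ``a`` in place.

    Strictly online exponential moving averages of the instantaneous
    layer mean and layer variance — O(N), no batch dependence.
    """
    m = p.stats_momentum
    state.mu = m * state.mu + (1.0 - m) * float(state.a.mean())
    state.var = m * state.var + (1.0 - m) * float(state.a.var())


def gate(state: AstrocyteState, p: AstrocyteParams) -> np.ndarray:
    """Normalise the astrocyte state and squash it into a gate in (0, 1).

    ``a_hat = (a - mu) / (sqrt(var) + eps)``;
    ``g = sigmoid(+-k_g * a_hat + beta_g)`` with the sign set by
    ``invert_gate``.  The gate is shared by every synapse afferent to
    its postsynaptic neuron.
    """
    a_hat = (state.a - state.mu) / (math.sqrt(max(state.var, 0.0)) + p.eps)
    slope = -p.k_g if p.invert_gate else p.k_g
    # the sigmoid saturates to exactly 0/1 in float64 for |z| > ~37;
    # clip to keep the gate strictly inside the open unit interval
    return np.clip(expit(slope * a_hat + p.beta_g), 1e-12, 1.0 - 1e-12)


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning-rate, weight-decay and homeostasis parameters."""

    eta: float = 0.05
    eta_decay: float = 0.0
    eta_b: float = 1e-3
    r_target: float = 0.1

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.eta_decay < 0:
            raise ValueError(f"eta_decay must be >= 0, got {self.eta_decay}")
        if self.eta_b < 0:
            raise ValueError(f"eta_b must be >= 0, got {self.eta_b}")
        if not (0.0 < self.r_target < 1.0):
            raise ValueError(f"r_target must be in (0, 1), got {self.r_target}")


def weight_update(
    W: np.ndarray,
    g: np.ndarray,
    M: np.ndarray,
    e: np.ndarray,
    cfg: PlasticityConfig,
) -> np.ndarray:
    """Four-factor update with decay.

    ``dW_ij = eta * g_i * M_i * e_ij - eta_decay * W_ij``; returns
    ``W + dW``.  ``g`` and ``M`` are indexed by the postsynaptic neuron;
    with the gate clamped to 1 and no decay this is exactly the plain
    three-factor (learning signal x trace) rule.
    """
    g = np.asarray(g, dtype=float)
    M = np.asarray(M, dtype=float)
    if e.shape != W.shape or g.shape != (W.shape[0],) or M.shape != (W.shape[0],):
        raise ValueError("weight_update: incompatible shapes")
    return W + (cfg.eta * (g * M))[:, None] * e - cfg.eta_decay * W


def homeostatic_bias(b: np.ndarray, r: np.ndarray, cfg: PlasticityConfig) -> np.ndarray:
    """Drive firing rates toward ``r_target`` through the bias.

    ``b' = b - eta_b * (r - r_target)``: over-active neurons are
    suppressed, silent neurons receive a positive bias drift; the rule
    is at a fixed point exactly when ``r == r_target``.
    """
    r = np.asarray(r, dtype=float)
    if b.shape != r.shape:
        raise ValueError("homeostatic_bias: shape mismatch")
    return b - cfg.eta_b * (r - cfg.r_target)
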