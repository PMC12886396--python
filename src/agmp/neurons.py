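"""Discrete-time leaky integrate-and-fire (LIF) neurons with adaptive thresholds.

The simulation step is fixed at ``dt = 1`` and every time constant is
expressed in steps.  A layer of ``n`` neurons carries four fast state
vectors: the membrane potential ``u``, the dynamic threshold ``theta``,
the binary spike vector ``s`` emitted at the current step, and an
exponentially averaged firing-rate estimate ``r`` used by the homeostatic
bias rule.

Update order within one step (the convention used throughout the package):

1. the spike vector ``s[t]`` was already computed from the pre-update
   membrane ``u[t]`` (it is stored in the state),
2. ``u[t+1] = alpha * u[t] + I[t] + b - theta[t] * s[t]`` (soft reset:
   the threshold is subtracted, supra-threshold excess is preserved),
3. ``theta[t+1] = theta0 + rho * (theta[t] - theta0) + beta * s[t]``,
4. ``s[t+1] = H(u[t+1] - theta[t+1])`` with the boundary ``u == theta``
   counted as a spike (``H(0) = 1``) for determinism.

With ``beta = 0`` the threshold stays pinned at ``theta0`` and the layer
is a plain LIF layer; ``beta > 0`` gives the adaptive-threshold (ALIF)
variant whose threshold increments after each spike and relaxes back to
baseline with rate ``rho``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "LayerState",
    "spike",
    "step_membrane",
    "step_threshold",
    "update_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of a LIF/ALIF layer.

    Parameters
    ----------
    tau_m:
        Membrane time constant in simulation steps; the leak factor is
        ``alpha = exp(-dt / tau_m)``.
    theta0:
        Baseline firing threshold (dimensionless potential units), > 0.
    rho:
        Decay factor of the threshold adaptation, in ``[0, 1)``.
    beta:
        Threshold increment per emitted spike, >= 0.  ``beta == 0``
        reduces the model to plain LIF.
    dt:
        Simulation step; fixed at 1 unit throughout the package.
    """

    tau_m: float = 20.0
    theta0: float = 1.0
    rho: float = 0.95
    beta: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_m > 0 and math.isfinite(self.tau_m)):
            raise ValueError(f"tau_m must be positive and finite, got {self.tau_m}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"leak factor alpha={self.alpha} outside (0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.theta0 <= 0:
            raise ValueError(f"theta0 must be > 0, got {self.theta0}")

    @property
    def alpha(self) -> float:
        """Membrane leak factor ``exp(-dt / tau_m)``."""
        return math.exp(-self.dt / self.tau_m)

    @property
    def is_lif(self) -> bool:
        return self.beta == 0.0


@dataclass
class LayerState:
    """Fast per-neuron state of one spiking layer.

    Invariant: ``s == spike(u, theta)`` — the stored spike vector is the
    one generated from the stored membrane and threshold.
    """

    u: np.ndarray
    theta: np.ndarray
    s: np.ndarray
    r: np.ndarray

    @classmethod
    def zeros(cls, n: int, params: NeuronParams) -> "LayerState":
        """Neutral initial condition: u = 0, theta = theta0, s = 0, r = 0."""
        u = np.zeros(n)
        theta = np.full(n, params.theta0)
        return cls(u=u, theta=theta, s=spike(u, theta), r=np.zeros(n))

    def copy(self) -> "LayerState":
        return LayerState(self.u.copy(), self.theta.copy(), self.s.copy(), self.r.copy())

    @property
    def n(self) -> int:
        return self.u.shape[0]

    def to_dict(self) -> dict[str, np.ndarray]:
        return {"u": self.u, "theta": self.theta, "s": self.s, "r": self.r}

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray]) -> "LayerState":
        return cls(
            u=np.asarray(d["u"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            s=np.asarray(d["s"], dtype=float),
            r=np.asarray(d["r"], dtype=float),
        )


def spike(u: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Deterministic threshold crossing: ``H(u - theta)`` with ``H(0) = 1``.

    Returns a float {0, 1} vector; a neuron fires exactly when its
    membrane potential reaches or exceeds its threshold.
    """
    u = np.asarray(u, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if u.shape != theta.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs theta {theta.shape}")
    return (u >= theta).astype(float)


def step_membrane(
    state: LayerState,
    params: NeuronParams,
    presyn_input: np.ndarray,
    bias: np.ndarray,
) -> LayerState:
    """Advance a layer by one step given the summed presynaptic drive.

    ``presyn_input`` is the already-weighted spike sum ``W @ x`` computed
    by the caller.  The spike stored in ``state.s`` (generated from the
    pre-update membrane) drives the soft reset and threshold adaptation;
    the returned state carries the new spikes generated from the updated
    membrane and threshold.  The firing-rate estimate ``r`` is copied
    unchanged — callers advance it separately with :func:`update_rate`.
    """
    presyn_input = np.asarray(presyn_input, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if presyn_input.shape != state.u.shape or bias.shape != state.u.shape:
        raise ValueError("presyn_input/bias shape does not match layer size")
    if not (np.all(np.isfinite(presyn_input)) and np.all(np.isfinite(bias))):
        raise ValueError("non-finite presynaptic input or bias")

    u_new = params.alpha * state.u + presyn_input + bias - state.theta * state.s
    theta_new = step_threshold(state, params)
    s_new = spike(u_new, theta_new)
    return LayerState(u=u_new, theta=theta_new, s=s_new, r=state.r.copy())


def step_threshold(state: LayerState, params: NeuronParams) -> np.ndarray:
    """Adaptive-threshold relaxation plus post-spike increment.

    ``theta' = theta0 + rho * (theta - theta0) + beta * s``; with
    ``beta = 0`` and ``theta`` initialised at ``theta0`` the threshold is
    exactly constant.
    """
    return params.theta0 + params.rho * (state.theta - params.theta0) + params.beta * state.s


def update_rate(state: LayerState, rate_momentum: float) -> np.ndarray:
    """Exponential moving average of the spike train, ``r in [0, 1]``."""
    if not (0.0 < rate_momentum < 1.0):
        raise ValueError(f"rate_momentum must be in (0, 1), got {rate_momentum}")
    return rate_momentum * state.r + (1.0 - rate_momentum) * state.s
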