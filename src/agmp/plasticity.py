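"""Surrogate derivative, eligibility traces, and broadcast learning signals.

These are the first three factors of the plasticity rule:

* a triangular surrogate pseudo-derivative ``psi`` of the spike function,
  evaluated at the membrane potential that generated the current spikes;
* a per-synapse eligibility trace ``e_ij`` — a fading memory of the
  correlation between the postsynaptic pseudo-derivative and presynaptic
  spikes, updated recursively so nothing indexed by time is stored;
* a modulatory learning signal ``M`` obtained by projecting the output
  error through a fixed random feedback matrix ``B`` (error broadcast /
  feedback alignment) instead of the transposed forward weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurrogateParams",
    "EligibilityState",
    "BroadcastMatrix",
    "surrogate_derivative",
    "update_trace",
    "output_error",
    "broadcast",
]


@dataclass(frozen=True)
class SurrogateParams:
    """Triangular pseudo-derivative: peak ``gamma`` at threshold, support
    ``2 * width`` around it."""

    gamma: float = 0.3
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")


def surrogate_derivative(
    u: np.ndarray, theta: np.ndarray, p: SurrogateParams
) -> np.ndarray:
    """``psi = gamma * max(0, 1 - |u - theta| / width)``.

    Piecewise-linear window centred on the firing threshold; the smooth
    stand-in for the Heaviside derivative used during learning.
    """
    u = np.asarray(u, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if u.shape != theta.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs theta {theta.shape}")
    return p.gamma * np.maximum(0.0, 1.0 - np.abs(u - theta) / p.width)


@dataclass
class EligibilityState:
    """Per-synapse fading traces ``e`` of shape [n_post, n_pre].

    ``lambda_e = exp(-dt / tau_e)`` is the per-step decay.  For binary
    inputs and ``psi <= gamma`` the trace magnitude is bounded by
    ``gamma / (1 - lambda_e)``.
    """

    e: np.ndarray
    lambda_e: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_e < 1.0):
            raise ValueError(f"lambda_e must be in (0, 1), got {self.lambda_e}")

    @classmethod
    def zeros(cls, n_post: int, n_pre: int, tau_e: float) -> "EligibilityState":
        if tau_e <= 0:
            raise ValueError(f"tau_e must be > 0, got {tau_e}")
        return cls(e=np.zeros((n_post, n_pre)), lambda_e=math.exp(-1.0 / tau_e))

    @property
    def tau_e(self) -> float:
        """Eligibility time constant in steps, ``-1 / ln(lambda_e)``."""
        return -1.0 / math.log(self.lambda_e)

    def copy(self) -> "EligibilityState":
        return EligibilityState(self.e.copy(), self.lambda_e)


def update_trace(
    es: EligibilityState, psi: np.ndarray, x_pre: np.ndarray
) -> EligibilityState:
    """Recursive trace update ``e' = lambda_e * e + outer(psi, x_pre)``.

    Equivalent (by unrolling) to the explicit fading-memory sum
    ``e[T] = sum_t lambda_e**(T - t) * psi[t] (x) x_pre[t]`` but computed
    forward in time with constant memory.
    """
    psi = np.asarray(psi, dtype=float)
    x_pre = np.asarray(x_pre, dtype=float)
    if (psi.shape[0], x_pre.shape[0]) != es.e.shape:
        raise ValueError(
            f"trace shape {es.e.shape} incompatible with psi {psi.shape} / x {x_pre.shape}"
        )
    return EligibilityState(es.lambda_e * es.e + np.outer(psi, x_pre), es.lambda_e)


@dataclass(frozen=True)
class BroadcastMatrix:
    """Fixed random feedback matrix ``B`` of shape [n_hidden, n_output].

    Drawn once at construction from a zero-mean distribution with entry
    standard deviation ``1 / sqrt(n_output)`` (variance equal to the
    reciprocal of the projection fan-in, so the broadcast signal keeps
    the variance of the output error) and never updated afterwards.  The
    seed is retained so the matrix can be reconstructed exactly.
    """

    B: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.B.setflags(write=False)

    @classmethod
    def create(
        cls,
        n_hidden: int,
        n_output: int,
        seed: int,
        distribution: str = "gaussian",
        scale: float | None = None,
    ) -> "BroadcastMatrix":
        """Draw B from its seed. ``scale`` overrides the entry std."""
        if scale is None:
            scale = 1.0 / math.sqrt(n_output)
        rng = np.random.default_rng(seed)
        if distribution == "gaussian":
            B = rng.normal(0.0, scale, size=(n_hidden, n_output))
        elif distribution == "uniform":
            half = math.sqrt(3.0) * scale  # uniform on [-a, a] has std a/sqrt(3)
            B = rng.uniform(-half, half, size=(n_hidden, n_output))
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        return cls(B=B, seed=int(seed))


def output_error(y: np.ndarray, y_target: np.ndarray) -> np.ndarray:
    """Per-step output error ``delta = y - y_target``.

    For a softmax readout and a one-hot target the components sum to 0.
    """
    y = np.asarray(y, dtype=float)
    y_target = np.asarray(y_target, dtype=float)
    if y.shape != y_target.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs target {y_target.shape}")
    return y - y_target


def broadcast(B: BroadcastMatrix, delta_out: np.ndarray) -> np.ndarray:
    """Project the output error to hidden neurons: ``M = B @ delta``."""
    delta_out = np.asarray(delta_out, dtype=float)
    if B.B.shape[1] != delta_out.shape[0]:
        raise ValueError(
            f"broadcast shape {B.B.shape} incompatible with error {delta_out.shape}"
        )
    return B.B @ delta_out
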