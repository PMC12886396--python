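"""Experiment drivers: single-task training, the class-incremental split
protocol, ablation variants, and the timescale sweep.

A :class:`ModelConfig` bundles every model-side knob (architecture,
neuron/surrogate/astrocyte/plasticity parameters, variant) so a run is
fully determined by ``(TaskSpec, ModelConfig, seed)``.  The seed drives
network initialisation and the per-sample noise stream of the task
generator; the task layout (class prototypes) is pinned by
``TaskSpec.seed`` so multi-seed runs vary only sample noise and
initial weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neurons import NeuronParams
from .plasticity import SurrogateParams
from .astrocyte import AstrocyteParams, PlasticityConfig
from .network import NetworkSpec, AGMPNetwork, VARIANTS
from .tasks import TaskSpec, TaskStream, make_split_stream
from .metrics import ContinualReport, average_accuracy, forgetting

__all__ = [
    "ModelConfig",
    "run_single_task",
    "run_continual",
    "run_continual_multiseed",
    "run_timescale_sweep",
]

_GATE_BINS = np.linspace(0.0, 1.0, 21)


@dataclass(frozen=True)
class ModelConfig:
    """Model-side configuration of an experiment."""

    hidden: tuple[int, ...] = (100,)
    kind: str = "lif"
    recurrent: bool = False
    neuron: NeuronParams = field(default_factory=NeuronParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    astro: AstrocyteParams = field(default_factory=AstrocyteParams)
    plast: PlasticityConfig = field(default_factory=PlasticityConfig)
    tau_e: float | None = None
    rate_momentum: float = 0.99
    variant: str = "full"
    gate_readout: bool = True

    def build(self, n_in: int, n_out: int, seed: int) -> AGMPNetwork:
        variant = self.variant
        plast = self.plast
        if variant == "no_homeostasis":
            plast = replace(plast, eta_b=0.0)
        spec = NetworkSpec.feedforward(
            n_in, self.hidden, n_out, kind=self.kind, recurrent=self.recurrent, seed=seed
        )
        return AGMPNetwork(
            spec,
            neuron=self.neuron,
            surrogate=self.surrogate,
            astro=self.astro,
            plast=plast,
            tau_e=self.tau_e,
            rate_momentum=self.rate_momentum,
            variant=variant,
            gate_readout=self.gate_readout,
        )

    def with_variant(self, variant: str) -> "ModelConfig":
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        return replace(self, variant=variant)


def _gate_histogram(net: AGMPNetwork) -> np.ndarray:
    gates = np.concatenate(
        [l.astro.g for l in net.layers if l.astro.g is not None]
    )
    return np.histogram(gates, bins=_GATE_BINS)[0].astype(float)


def run_single_task(
    task_spec: TaskSpec,
    model: ModelConfig = ModelConfig(),
    seed: int = 0,
    task_index: int = 0,
    max_train_samples: int | None = None,
    stream: TaskStream | None = None,
    supervise_from: int = 0,
) -> dict:
    """Train on one task of the stream and report its test accuracy.

    The readout still spans all classes (single head), so this is the
    stationary baseline of the continual protocol.  ``supervise_from``
    delays the teaching signal to the tail of each sample (delayed
    supervision probes temporal credit assignment through the trace).
    """
    if stream is None:
        stream = make_split_stream(replace(task_spec, sample_seed=_sample_seed(seed)))
    task = stream.tasks[task_index]
    net = model.build(task_spec.n_in, task_spec.n_classes_total, seed)
    losses = []
    n = len(task.train_y) if max_train_samples is None else min(max_train_samples, len(task.train_y))
    for x, yl in zip(task.train_x[:n], task.train_y[:n]):
        losses.append(
            net.train_sequence(x, int(yl), supervise_from=supervise_from)["loss"]
        )
    acc = net.evaluate(task.test_x, task.test_y, count_ops=True)
    return {
        "accuracy": acc,
        "losses": losses,
        "n_train": n,
        "synops": net.synops,
        "spike_count": net.spike_count,
        "net": net,
    }


def run_continual(
    task_spec: TaskSpec,
    model: ModelConfig = ModelConfig(),
    seed: int = 0,
    stream: TaskStream | None = None,
    max_train_samples_per_task: int | None = None,
) -> ContinualReport:
    """Sequentially train all tasks (single head, Class-IL), evaluating
    every seen task after each stage."""
    if stream is None:
        stream = make_split_stream(replace(task_spec, sample_seed=_sample_seed(seed)))
    K = stream.n_tasks
    net = model.build(task_spec.n_in, task_spec.n_classes_total, seed)
    acc = np.full((K, K), np.nan)
    gate_hist = np.zeros(len(_GATE_BINS) - 1)
    for k, task in enumerate(stream.tasks):
        n = len(task.train_y)
        if max_train_samples_per_task is not None:
            n = min(n, max_train_samples_per_task)
        for i, (x, yl) in enumerate(zip(task.train_x[:n], task.train_y[:n])):
            net.train_sequence(x, int(yl))
            if i % 25 == 0:
                gate_hist += _gate_histogram(net)
        for j in range(k + 1):
            tj = stream.tasks[j]
            acc[k, j] = net.evaluate(tj.test_x, tj.test_y, count_ops=(k == K - 1))
    return ContinualReport(
        acc=acc,
        A_T=average_accuracy(acc),
        F_T=forgetting(acc) if K >= 2 else 0.0,
        spike_count=net.spike_count,
        synops=net.synops,
        gate_hist=gate_hist,
        variant=model.variant,
        seed=seed,
    )


def run_continual_multiseed(
    task_spec: TaskSpec,
    model: ModelConfig = ModelConfig(),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    **kwargs,
) -> list[ContinualReport]:
    return [run_continual(task_spec, model, seed=s, **kwargs) for s in seeds]


def run_timescale_sweep(
    task_spec: TaskSpec,
    model: ModelConfig = ModelConfig(),
    tau_e_grid: tuple[float, ...] = (20.0,),
    tau_a_grid: tuple[float, ...] = (20.0, 200.0, 2000.0),
    seeds: tuple[int, ...] = (0, 1, 2),
    **kwargs,
) -> pd.DataFrame:
    """Forgetting/accuracy over a (tau_e, tau_a) grid; one row per
    (tau_e, tau_a, seed).  Supports the timescale-separation heatmap."""
    rows = []
    for tau_e in tau_e_grid:
        for tau_a in tau_a_grid:
            m = replace(model, tau_e=tau_e, astro=replace(model.astro, tau_a=tau_a))
            for s in seeds:
                rep = run_continual(task_spec, m, seed=s, **kwargs)
                rows.append(
                    {
                        "tau_e": tau_e,
                        "tau_a": tau_a,
                        "ratio": tau_a / tau_e,
                        "seed": s,
                        "A_T": rep.A_T,
                        "F_T": rep.F_T,
                    }
                )
    return pd.DataFrame(rows)


def _sample_seed(seed: int) -> int:
    # decorrelate the data-noise stream from the weight-init stream
    return int(np.random.SeedSequence([seed, 0xA5]).generate_state(1)[0] & 0x7FFFFFFF)
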