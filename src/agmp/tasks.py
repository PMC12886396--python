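"""Synthetic Poisson-encoded spiking classification streams.

Each class is defined by a fixed prototype: a random subset of input
neurons that fire with probability ``rate_high`` per step while the rest
fire at ``rate_low``.  Samples are independent Bernoulli (binned
Poisson) draws from the prototype's rate vector, with optional per-sample
"jitter" that flips each neuron's prototype membership with small
probability.  Classes are partitioned contiguously into sequential
tasks with disjoint label sets — the class-incremental (Class-IL)
split protocol in which a single readout head covers all classes from
the start.

Two independent seed streams derive from ``TaskSpec.seed``: one for the
class prototypes (the task layout) and one for per-sample noise, so the
layout can be held fixed while data are resampled (set ``sample_seed``).
Regeneration from an identical spec is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import h5py

__all__ = [
    "TaskSpec",
    "Task",
    "TaskStream",
    "make_prototypes",
    "encode_poisson",
    "make_split_stream",
    "export_hdf5",
    "load_hdf5",
]


@dataclass(frozen=True)
class TaskSpec:
    """Generator parameters for a split-task spiking stream.

    Defaults give a 5-task / 2-classes-per-task protocol on 100 input
    neurons: 50-step samples, prototype neurons firing at 0.5 per step
    against a 0.05 background, 20% of inputs active per prototype,
    250 training and 50 test samples per class, and 2% membership
    jitter per sample.
    """

    n_in: int = 100
    n_classes_total: int = 10
    n_tasks: int = 5
    T: int = 50
    rate_high: float = 0.5
    rate_low: float = 0.05
    active_frac: float = 0.2
    samples_per_class: int = 250
    test_samples_per_class: int = 50
    jitter: float = 0.02
    seed: int = 0
    sample_seed: int | None = None  # overrides the derived per-sample noise stream

    def __post_init__(self) -> None:
        if self.n_classes_total % self.n_tasks != 0:
            raise ValueError(
                f"{self.n_classes_total} classes not divisible into {self.n_tasks} tasks"
            )
        if not (0.0 <= self.rate_low < self.rate_high <= 1.0):
            raise ValueError("need 0 <= rate_low < rate_high <= 1")
        if not (0.0 <= self.jitter <= 1.0):
            raise ValueError(f"jitter must be in [0, 1], got {self.jitter}")
        if self.T < 1 or self.n_in < 1:
            raise ValueError("T and n_in must be >= 1")
        if math.ceil(self.active_frac * self.n_in) < 1:
            raise ValueError(f"active_frac={self.active_frac} activates no input neuron")

    @property
    def classes_per_task(self) -> int:
        return self.n_classes_total // self.n_tasks

    @property
    def n_active(self) -> int:
        return math.ceil(self.active_frac * self.n_in)

    def _seed_streams(self) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
        proto_ss, sample_ss = np.random.SeedSequence(self.seed).spawn(2)
        if self.sample_seed is not None:
            sample_ss = np.random.SeedSequence(self.sample_seed)
        return proto_ss, sample_ss


@dataclass
class Task:
    """One stage of the stream: disjoint classes, train/test splits."""

    classes: tuple[int, ...]
    train_x: np.ndarray  # uint8 [n_train, T, n_in]
    train_y: np.ndarray  # int [n_train] (global class labels)
    test_x: np.ndarray
    test_y: np.ndarray


@dataclass
class TaskStream:
    """Ordered sequence of tasks plus the class->prototype map."""

    spec: TaskSpec
    prototypes: dict[int, np.ndarray]  # class -> boolean mask [n_in]
    tasks: list[Task]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


def make_prototypes(spec: TaskSpec) -> dict[int, np.ndarray]:
    """Draw each class's high-rate mask: ``ceil(active_frac * n_in)``
    input neurons chosen without replacement (classes may overlap)."""
    proto_ss, _ = spec._seed_streams()
    rng = np.random.default_rng(proto_ss)
    protos: dict[int, np.ndarray] = {}
    for c in range(spec.n_classes_total):
        idx = rng.choice(spec.n_in, size=spec.n_active, replace=False)
        mask = np.zeros(spec.n_in, dtype=bool)
        mask[idx] = True
        protos[c] = mask
    return protos


def encode_poisson(
    mask: np.ndarray, spec: TaskSpec, sample_seed: int | np.random.Generator
) -> np.ndarray:
    """One spike tensor [T, n_in] drawn from the prototype's rates.

    Jitter flips each neuron's mask membership for this sample with
    probability ``spec.jitter``; each (step, neuron) then spikes
    independently with probability ``rate_high`` (in-mask) or
    ``rate_low``.
    """
    rng = (
        sample_seed
        if isinstance(sample_seed, np.random.Generator)
        else np.random.default_rng(sample_seed)
    )
    mask = np.asarray(mask, dtype=bool)
    eff = mask ^ (rng.random(spec.n_in) < spec.jitter)
    p = np.where(eff, spec.rate_high, spec.rate_low)
    return (rng.random((spec.T, spec.n_in)) < p).astype(np.uint8)


def make_split_stream(spec: TaskSpec) -> TaskStream:
    """Build the full Class-IL stream: contiguous class partition,
    per-task train/test splits, shuffled training order within a task."""
    protos = make_prototypes(spec)
    _, sample_ss = spec._seed_streams()
    rng = np.random.default_rng(sample_ss)
    cpt = spec.classes_per_task
    tasks: list[Task] = []
    for k in range(spec.n_tasks):
        classes = tuple(range(k * cpt, (k + 1) * cpt))
        xs, ys = [], []
        for c in classes:
            for _ in range(spec.samples_per_class):
                xs.append(encode_poisson(protos[c], spec, rng))
                ys.append(c)
        order = rng.permutation(len(xs))
        train_x = np.stack(xs)[order]
        train_y = np.asarray(ys, dtype=int)[order]
        xs, ys = [], []
        for c in classes:
            for _ in range(spec.test_samples_per_class):
                xs.append(encode_poisson(protos[c], spec, rng))
                ys.append(c)
        tasks.append(
            Task(
                classes=classes,
                train_x=train_x,
                train_y=train_y,
                test_x=np.stack(xs),
                test_y=np.asarray(ys, dtype=int),
            )
        )
    return TaskStream(spec=spec, prototypes=protos, tasks=tasks)


def export_hdf5(stream: TaskStream, path: str) -> None:
    """Write the stream (spikes as uint8) plus its spec for bit-exact reload."""
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(asdict(stream.spec))
        pg = f.create_group("prototypes")
        for c, mask in stream.prototypes.items():
            pg.create_dataset(str(c), data=mask.astype(np.uint8))
        for k, task in enumerate(stream.tasks):
            grp = f.create_group(f"task_{k}")
            grp.attrs["classes"] = list(task.classes)
            grp.create_dataset("train_x", data=task.train_x, compression="gzip")
            grp.create_dataset("train_y", data=task.train_y)
            grp.create_dataset("test_x", data=task.test_x, compression="gzip")
            grp.create_dataset("test_y", data=task.test_y)


def load_hdf5(path: str) -> TaskStream:
    with h5py.File(path, "r") as f:
        spec_d = json.loads(f.attrs["spec"])
        spec = TaskSpec(**spec_d)
        protos = {
            int(c): f["prototypes"][c][()].astype(bool) for c in f["prototypes"]
        }
        tasks = []
        for k in range(spec.n_tasks):
            grp = f[f"task_{k}"]
            tasks.append(
                Task(
                    classes=tuple(int(c) for c in grp.attrs["classes"]),
                    train_x=grp["train_x"][()],
                    train_y=grp["train_y"][()],
                    test_x=grp["test_x"][()],
                    test_y=grp["test_y"][()],
                )
            )
    return TaskStream(spec=spec, prototypes=protos, tasks=tasks)
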