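"""Continual-learning metrics and the evaluation report container.

The accuracy matrix ``acc`` is indexed ``acc[k, j]`` = test accuracy on
task ``j`` measured after finishing training on task ``k`` (0-based;
only the lower triangle ``j <= k`` is meaningful, the rest is NaN).

* Average accuracy ``A_T``: mean of the final row — mean accuracy over
  all tasks after the whole stream.
* Forgetting ``F_T``: for each non-final task, the drop from its best
  accuracy at any earlier stage to its final accuracy, floored at zero,
  averaged over tasks.  Zero when no task's accuracy ever declines;
  positive whenever any forgetting occurred.

Energy proxies: ``spike_count`` totals presynaptic spike events during
evaluation; ``synops`` charges each presynaptic spike one operation per
efferent synapse (spike x fan-out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["average_accuracy", "forgetting", "ContinualReport"]


def average_accuracy(acc: np.ndarray, n_tasks: int | None = None) -> float:
    """Mean final-stage accuracy ``A_T = mean_j acc[T-1, j]``."""
    acc = np.asarray(acc, dtype=float)
    n_tasks = n_tasks or acc.shape[0]
    final = acc[n_tasks - 1, :n_tasks]
    if np.any(np.isnan(final)):
        raise ValueError("final row of the accuracy matrix is not fully populated")
    return float(final.mean())


def forgetting(acc: np.ndarray, n_tasks: int | None = None) -> float:
    """Mean maximum-drop forgetting over non-final tasks.

    ``F_T = mean_{j<T-1} max(0, max_{j<=k<T-1} acc[k, j] - acc[T-1, j])``.
    Requires at least two tasks.
    """
    acc = np.asarray(acc, dtype=float)
    n_tasks = n_tasks or acc.shape[0]
    if n_tasks < 2:
        raise ValueError("forgetting requires at least 2 tasks")
    drops = []
    for j in range(n_tasks - 1):
        past = acc[j : n_tasks - 1, j]
        if np.any(np.isnan(past)) or np.isnan(acc[n_tasks - 1, j]):
            raise ValueError("accuracy matrix lower triangle is not fully populated")
        drops.append(max(0.0, float(past.max() - acc[n_tasks - 1, j])))
    return float(np.mean(drops))


@dataclass
class ContinualReport:
    """Everything a split-protocol run produces."""

    acc: np.ndarray  # [n_tasks, n_tasks], NaN above the diagonal
    A_T: float
    F_T: float
    spike_count: float
    synops: float
    gate_hist: np.ndarray  # counts over 20 bins on [0, 1]
    variant: str = "full"
    seed: int = 0

    @property
    def n_tasks(self) -> int:
        return self.acc.shape[0]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "n_tasks": self.n_tasks,
            "A_T": self.A_T,
            "F_T": self.F_T,
            "spike_count": self.spike_count,
            "synops": self.synops,
            "acc": [[None if np.isnan(v) else v for v in row] for row in self.acc],
            "gate_hist": self.gate_hist.tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ContinualReport":
        acc = np.array(
            [[np.nan if v is None else v for v in row] for row in d["acc"]], dtype=float
        )
        return cls(
            acc=acc,
            A_T=d["A_T"],
            F_T=d["F_T"],
            spike_count=d["spike_count"],
            synops=d["synops"],
            gate_hist=np.asarray(d["gate_hist"]),
            variant=d.get("variant", "full"),
            seed=d.get("seed", 0),
        )

    def acc_csv(self, path: str) -> None:
        n = self.n_tasks
        header = "stage," + ",".join(f"task_{j}" for j in range(n))
        rows = [
            f"{k}," + ",".join("" if np.isnan(v) else f"{v:.4f}" for v in self.acc[k])
            for k in range(n)
        ]
        with open(path, "w") as f:
            f.write(header + "\n" + "\n".join(rows) + "\n")
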