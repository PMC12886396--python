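"""YAML experiment configuration.

A config file has up to seven sections, each optional and each mapping
directly onto a parameter dataclass; omitted keys keep the package
defaults::

    task:       {n_in: 100, n_tasks: 5, T: 50, rate_high: 0.5, ...}
    model:      {hidden: [100], kind: lif, recurrent: false, variant: full}
    neuron:     {tau_m: 20.0, theta0: 1.0, rho: 0.95, beta: 0.0}
    surrogate:  {gamma: 0.3, width: 1.0}
    astrocyte:  {tau_a: 2000.0, eta_u: 0.1, k_g: 1.0, invert_gate: true, ...}
    plasticity: {eta: 0.05, eta_decay: 0.0, eta_b: 0.001, r_target: 0.1}
    harness:    {max_train_samples_per_task: null, seeds: [0, 1, 2]}
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .neurons import NeuronParams
from .plasticity import SurrogateParams
from .astrocyte import AstrocyteParams, PlasticityConfig
from .harness import ModelConfig
from .tasks import TaskSpec

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    task: TaskSpec = field(default_factory=TaskSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    max_train_samples_per_task: int | None = None
    seeds: tuple[int, ...] = (0,)


def load_config(path: str | None) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file (or defaults)."""
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    task = TaskSpec(**(raw.get("task") or {}))
    model_kw = dict(raw.get("model") or {})
    if "hidden" in model_kw:
        model_kw["hidden"] = tuple(model_kw["hidden"])
    model = ModelConfig(
        neuron=NeuronParams(**(raw.get("neuron") or {})),
        surrogate=SurrogateParams(**(raw.get("surrogate") or {})),
        astro=AstrocyteParams(**(raw.get("astrocyte") or {})),
        plast=PlasticityConfig(**(raw.get("plasticity") or {})),
        **model_kw,
    )
    harness = raw.get("harness") or {}
    return ExperimentConfig(
        task=task,
        model=model,
        max_train_samples_per_task=harness.get("max_train_samples_per_task"),
        seeds=tuple(harness.get("seeds", (0,))),
    )


def save_config(cfg: ExperimentConfig, path: str) -> None:
    doc = {
        "task": asdict(cfg.task),
        "model": {
            "hidden": list(cfg.model.hidden),
            "kind": cfg.model.kind,
            "recurrent": cfg.model.recurrent,
            "variant": cfg.model.variant,
            "tau_e": cfg.model.tau_e,
            "rate_momentum": cfg.model.rate_momentum,
            "gate_readout": cfg.model.gate_readout,
        },
        "neuron": asdict(cfg.model.neuron),
        "surrogate": asdict(cfg.model.surrogate),
        "astrocyte": asdict(cfg.model.astro),
        "plasticity": asdict(cfg.model.plast),
        "harness": {
            "max_train_samples_per_task": cfg.max_train_samples_per_task,
            "seeds": list(cfg.seeds),
        },
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
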