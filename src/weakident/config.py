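"""Experiment configurations tying models, noise, test functions together.

The defaults encode the two benchmark studies:

* blood-tissue diffusion: k12=5, k21=1, Ve=6, x(0)=(1,0), horizon [0,2]
  (the dynamics decay within about one time unit and the printed
  test-function radii 0.52-0.8 fit inside the window), 40 observations for
  identifiability studies (400 for dense-grid accuracy curves), 12th-order
  polynomial test functions with radius a=0.52, e-grid 0.5-20%.
* SIR: N=10,000, I0=1, beta=5.5/N, recovery rate alpha=5, 31 daily
  observations on [0, 30], polynomial test functions with radius
  a = 0.25 * horizon, additive e-grid 10-200%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .models import ODEModel, Trajectory, make_model, simulate, coefficient_map_blood
from .noise import ADDITIVE
from .test_functions import TestFunctionFamily, TestFunctionGrid, place_test_functions
from .weak_wendy import (
    WeakIOSystem,
    build_weak_blood_system,
    build_weak_sir_system,
)

__all__ = ["ExperimentConfig", "blood_config", "sir_config", "build_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one simulation study."""

    model: str
    model_params: dict[str, Any]
    n_obs: int
    horizon: float
    noise_kind: str
    e_values: tuple[float, ...]
    q_values: tuple[float, ...]
    d: int
    family: str
    a: float
    eta: float
    k: int | None
    seed: int

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["model_params"] = {
            k: (list(v) if isinstance(v, (tuple, list, np.ndarray)) else v)
            for k, v in out["model_params"].items()
        }
        out["e_values"] = list(out["e_values"])
        out["q_values"] = list(out["q_values"])
        return out


def blood_config(**overrides) -> ExperimentConfig:
    """Default blood-tissue identifiability study (40 observations)."""
    cfg = ExperimentConfig(
        model="blood_tissue",
        model_params={"k12": 5.0, "k21": 1.0, "ve": 6.0, "ic": (1.0, 0.0)},
        n_obs=40,
        horizon=2.0,
        noise_kind=ADDITIVE,
        e_values=tuple(np.arange(0.005, 0.2001, 0.005).round(4)),
        q_values=tuple(np.arange(0.01, 1.001, 0.01).round(4)),
        d=1000,
        family="poly12",
        a=0.52,
        eta=9.0,
        k=None,
        seed=0,
    )
    return cfg.replace(**overrides) if overrides else cfg


def sir_config(**overrides) -> ExperimentConfig:
    """Default SIR identifiability study (31 daily observations)."""
    cfg = ExperimentConfig(
        model="sir",
        model_params={"beta": 5.5 / 10_000, "alpha": 5.0, "n_pop": 10_000.0,
                      "i0": 1.0},
        n_obs=31,
        horizon=30.0,
        noise_kind=ADDITIVE,
        e_values=tuple(np.arange(0.1, 2.001, 0.1).round(4)),
        q_values=tuple(np.arange(0.01, 1.001, 0.01).round(4)),
        d=1000,
        family="poly12",
        a=0.25 * 30.0,
        eta=9.0,
        k=None,
        seed=0,
    )
    return cfg.replace(**overrides) if overrides else cfg


DEFAULT_CONFIGS = {"blood_tissue": blood_config, "sir": sir_config}


def build_experiment(
    config: ExperimentConfig,
) -> tuple[ODEModel, WeakIOSystem, np.ndarray, Trajectory, TestFunctionGrid, np.ndarray]:
    """Instantiate (model, weak system, times, truth, test functions, w_true)."""
    times = np.linspace(0.0, config.horizon, config.n_obs)
    if config.model == "blood_tissue":
        p = config.model_params
        model = make_model("blood_tissue", k12=p["k12"], k21=p["k21"], ve=p["ve"],
                           ic=p.get("ic", (1.0, 0.0)))
        system = build_weak_blood_system()
        w_true = coefficient_map_blood(p["k12"], p["k21"], p["ve"])
    elif config.model == "sir":
        p = config.model_params
        model = make_model("sir", beta=p["beta"], alpha=p["alpha"],
                           n_pop=p["n_pop"], i0=p["i0"])
        system = build_weak_sir_system(alpha_known=p["alpha"],
                                       s0=p["n_pop"] - p["i0"])
        w_true = np.array([p["beta"]])
    else:
        raise KeyError(f"unknown model {config.model!r}")
    truth = simulate(model, times)
    family = TestFunctionFamily(family=config.family, a=config.a, eta=config.eta)
    tf = place_test_functions(times, family, config.k)
    return model, system, times, truth, tf, w_true
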