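"""Canned Monte-Carlo study drivers for the two benchmark systems.

Thin wrappers over :func:`weakident.identifiability.summaries_for_e_values`
with the benchmark defaults baked in; used by the CLI, the acceptance
script and the test suite.
"""

from __future__ import annotations

from typing import Sequence

from .config import blood_config, sir_config
from .identifiability import ReplicateSummary, summaries_for_e_values
from .noise import ADDITIVE

__all__ = ["blood_study", "sir_study"]


def blood_study(
    e_values: Sequence[float],
    n_obs: int = 40,
    d: int = 1000,
    seed: int = 0,
    family: str = "poly12",
    a: float = 0.52,
) -> list[ReplicateSummary]:
    """Blood-tissue Monte-Carlo summaries at each observation error ratio."""
    cfg = blood_config(n_obs=n_obs, family=family, a=a, d=d, seed=seed)
    return summaries_for_e_values(cfg, e_values, d, seed)


def sir_study(
    e_values: Sequence[float],
    noise_kind: str = ADDITIVE,
    d: int = 1000,
    seed: int = 0,
) -> list[ReplicateSummary]:
    """SIR Monte-Carlo summaries (31 daily observations) at each error ratio."""
    cfg = sir_config(noise_kind=noise_kind, d=d, seed=seed)
    return summaries_for_e_values(cfg, e_values, d, seed)
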