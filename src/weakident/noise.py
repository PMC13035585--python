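"""Noisy observation ensembles with a scale-free error parameterization.

The noise level is specified by the observation error ratio ``e``: for
additive Gaussian noise the error standard deviation is
``sigma = e * RMS(Omega)``, where Omega is the noiseless observed signal
and RMS is the root mean square computed with trapezoidal time
integration on the observation grid.  For multiplicative lognormal noise
the log-errors are N(0, e^2), i.e. ``e`` is directly the standard
deviation on the log scale (the observed signal is multiplied by
``exp(eta)``).

All randomness is driven by integer seeds; identical specs produce
byte-identical realizations.  ``generate_ensemble`` simulates one shared
truth trajectory and draws D independent noise realizations with
per-replicate seeds ``base_seed + replicate_index``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import ODEModel, Trajectory, simulate

__all__ = [
    "NoiseSpec",
    "ObservationSet",
    "ADDITIVE",
    "MULTIPLICATIVE",
    "rms",
    "sigma_from_e",
    "apply_noise",
    "generate_ensemble",
]

ADDITIVE = "additive_gaussian"
MULTIPLICATIVE = "multiplicative_lognormal"
_KINDS = (ADDITIVE, MULTIPLICATIVE)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class NoiseSpec:
    """Noise kind, observation error ratio e (dimensionless), and seed."""

    kind: str
    e: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; known: {_KINDS}")
        if self.e < 0:
            raise ValueError("observation error ratio e must be nonnegative")


@dataclass(eq=False)
class ObservationSet:
    """One noisy realization of an observed trajectory."""

    times: np.ndarray
    y: np.ndarray
    truth: np.ndarray
    spec: NoiseSpec
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.y) == len(self.truth)):
            raise ValueError("times, y and truth must share a length")


def rms(values: Sequence[float], times: Sequence[float]) -> float:
    """Root mean square of a sampled signal, sqrt( integral(v^2) / (T_M - T_0) ).

    The integral is trapezoidal on the observation grid.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size < 2 or times.size != values.size:
        raise ValueError("need at least 2 aligned samples for an RMS")
    span = times[-1] - times[0]
    return float(np.sqrt(np.trapezoid(values**2, times) / span))


def sigma_from_e(
    e: float, truth: Sequence[float], times: Sequence[float], kind: str = ADDITIVE
) -> float:
    """Noise scale implied by an observation error ratio.

    additive_gaussian       -> sigma = e * RMS(truth)
    multiplicative_lognormal-> sigma_log = e  (standard deviation of log-errors)
    """
    if e < 0:
        raise ValueError("e must be nonnegative")
    if kind == ADDITIVE:
        return e * rms(truth, times)
    if kind == MULTIPLICATIVE:
        return float(e)
    raise ValueError(f"unknown noise kind {kind!r}")


def apply_noise(truth: Sequence[float], times: Sequence[float], spec: NoiseSpec,
                replicate_id: int = 0) -> ObservationSet:
    """Corrupt a noiseless observed signal according to ``spec``."""
    truth = np.asarray(truth, dtype=float)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == ADDITIVE:
        sigma = sigma_from_e(spec.e, truth, times, ADDITIVE)
        y = truth + rng.normal(0.0, sigma, size=truth.size) if sigma > 0 else truth.copy()
    else:
        if np.any(truth <= 0):
            raise ValueError("multiplicative lognormal noise requires positive truth")
        if spec.e > 0:
            y = truth * np.exp(rng.normal(0.0, spec.e, size=truth.size))
        else:
            y = truth.copy()
    return ObservationSet(times=times, y=y, truth=truth, spec=spec,
                          replicate_id=replicate_id)


def generate_ensemble(
    model: ODEModel,
    times: Sequence[float],
    spec: NoiseSpec,
    d: int,
    truth: Trajectory | None = None,
) -> list[ObservationSet]:
    """D noisy replicates sharing one truth trajectory.

    Replicate k uses seed ``(spec.seed + k) mod 2^31`` so ensembles are
    reproducible and replicates independent.  A precomputed ``truth``
    trajectory may be passed to amortize the ODE solve across noise levels.
    """
    if d < 1:
        raise ValueError("replicate count D must be >= 1")
    if truth is None:
        truth = simulate(model, times)
    omega = truth.observed
    out = []
    for k in range(d):
        rep_spec = NoiseSpec(kind=spec.kind, e=spec.e, seed=(spec.seed + k) % _SEED_MOD)
        out.append(apply_noise(omega, truth.times, rep_spec, replicate_id=k))
    return out
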