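"""Benchmark ODE systems and their input-output reductions.

Two partially observed compartmental models are provided:

* ``blood_tissue`` — diffusion of a drug between blood (x1, observed) and
  tissue (x2, unobserved), with saturable decay in the blood::

      dx1/dt = -k12*x1 + k21*x2 - Ve*x1/(1 + x1)
      dx2/dt =  k12*x1 - k21*x2

  Eliminating x2 gives a second-order input-output equation in x1 whose
  coefficients are the identifiable combinations
  w1 = k21*Ve, w2 = k12 + k21, w3 = k12 + k21 + Ve.

* ``sir`` — the classic closed-population SIR epidemic with the infected
  compartment I observed; transmission rate beta is the estimand, the
  recovery rate alpha is treated as known.

The module also exposes a strong-form residual of each input-output
equation (evaluated with finite-difference derivatives of the observed
state) which serves as an independent validation oracle for the weak-form
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEModel",
    "Trajectory",
    "CoefficientMap",
    "InvalidParameterError",
    "SimulationError",
    "make_blood_model",
    "make_sir_model",
    "simulate",
    "coefficient_map_blood",
    "invert_coefficient_map_blood",
    "strong_io_residual",
    "MODEL_REGISTRY",
    "make_model",
]

# Truth trajectories must be accurate far beyond the measurement noise
# they will be corrupted with.
SOLVER_RTOL = 1e-10
SOLVER_ATOL = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraint."""


class SimulationError(RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


@dataclass(eq=False)
class ODEModel:
    """A fully specified ODE system with a single observed state."""

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    params: np.ndarray
    initial_state: np.ndarray
    observed_index: int
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if len(self.initial_state) != len(self.state_names):
            raise ValueError("initial_state length must match state_names")
        if not 0 <= self.observed_index < len(self.state_names):
            raise ValueError("observed_index out of range")


@dataclass(eq=False)
class Trajectory:
    """A simulated solution sampled on a time grid."""

    times: np.ndarray
    states: np.ndarray
    observed_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per time point")

    @property
    def observed(self) -> np.ndarray:
        """Noiseless observed state Omega(t)."""
        return self.states[:, self.observed_index]


@dataclass(frozen=True)
class CoefficientMap:
    """Map from mechanistic parameters p to identifiable combinations w."""

    forward: Callable[[np.ndarray], np.ndarray]
    w_names: tuple[str, ...]

    def __call__(self, p: Sequence[float]) -> np.ndarray:
        return self.forward(np.asarray(p, dtype=float))


def _blood_rhs(state: np.ndarray, params: np.ndarray) -> np.ndarray:
    x1, x2 = state
    k12, k21, ve = params
    flux = k12 * x1 - k21 * x2
    return np.array([-flux - ve * x1 / (1.0 + x1), flux])


def make_blood_model(
    k12: float = 5.0,
    k21: float = 1.0,
    ve: float = 6.0,
    ic: Sequence[float] = (1.0, 0.0),
) -> ODEModel:
    """Blood-tissue diffusion model.

    Defaults are the benchmark parameterization k12=5, k21=1, Ve=6 with the
    drug initially confined to the blood compartment, ic=(1, 0).
    """
    for name, val in (("k12", k12), ("k21", k21), ("Ve", ve)):
        if val < 0:
            raise InvalidParameterError(f"{name} must be nonnegative, got {val}")
    ic = np.asarray(ic, dtype=float)
    if ic.shape != (2,) or np.any(ic < 0):
        raise InvalidParameterError("ic must be a nonnegative 2-vector")
    return ODEModel(
        name="blood_tissue",
        state_names=("x1", "x2"),
        param_names=("k12", "k21", "Ve"),
        params=np.array([k12, k21, ve]),
        initial_state=ic,
        observed_index=0,
        rhs=_blood_rhs,
    )


def _sir_rhs(state: np.ndarray, params: np.ndarray) -> np.ndarray:
    s, i, _ = state
    beta, alpha = params
    infection = beta * s * i
    return np.array([-infection, infection - alpha * i, alpha * i])


def make_sir_model(
    beta: float = 5.5 / 10_000,
    alpha: float = 5.0,
    n_pop: float = 10_000.0,
    i0: float = 1.0,
) -> ODEModel:
    """Closed-population SIR model observed through I(t).

    Defaults reproduce the benchmark outbreak: N=10,000, I0=1, S0=N-1, R0=0,
    beta=5.5/N and recovery rate 5 (basic reproduction number 1.1).
    """
    if beta <= 0 or alpha <= 0:
        raise InvalidParameterError("beta and alpha must be positive")
    if not 0 < i0 < n_pop:
        raise InvalidParameterError("I0 must satisfy 0 < I0 < N")
    return ODEModel(
        name="sir",
        state_names=("S", "I", "R"),
        param_names=("beta", "alpha"),
        params=np.array([beta, alpha]),
        initial_state=np.array([n_pop - i0, i0, 0.0]),
        observed_index=1,
        rhs=_sir_rhs,
    )


def simulate(model: ODEModel, times: Sequence[float]) -> Trajectory:
    """Integrate ``model`` and sample the solution at ``times``.

    Uses LSODA with rtol=1e-10 / atol=1e-12 so that the integration error is
    negligible relative to any measurement noise later added to the output.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing vector")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    sol = solve_ivp(
        lambda t, u: model.rhs(u, model.params),
        (times[0], times[-1]),
        model.initial_state,
        t_eval=times,
        method="LSODA",
        rtol=SOLVER_RTOL,
        atol=SOLVER_ATOL,
    )
    if not sol.success:
        raise SimulationError(f"solver failed for {model.name}: {sol.message}")
    return Trajectory(times=times, states=sol.y.T, observed_index=model.observed_index)


def coefficient_map_blood(k12: float, k21: float, ve: float) -> np.ndarray:
    """Identifiable combinations of the blood model: (k21*Ve, k12+k21, k12+k21+Ve)."""
    if k12 < 0 or k21 < 0 or ve < 0:
        raise InvalidParameterError("rates must be nonnegative")
    return np.array([k21 * ve, k12 + k21, k12 + k21 + ve])


BLOOD_COEFFICIENT_MAP = CoefficientMap(
    forward=lambda p: coefficient_map_blood(*p), w_names=("w1", "w2", "w3")
)


def invert_coefficient_map_blood(w1: float, w2: float, w3: float) -> tuple[float, float, float]:
    """Invert (w1,w2,w3) -> (k12,k21,Ve); raises if the cell is infeasible.

    Ve = w3 - w2, k21 = w1/Ve, k12 = w2 - k21; all three must be positive.
    """
    ve = w3 - w2
    if ve <= 0:
        raise InvalidParameterError("w3 must exceed w2 (Ve > 0)")
    if w1 <= 0:
        raise InvalidParameterError("w1 must be positive")
    k21 = w1 / ve
    k12 = w2 - k21
    if k12 <= 0:
        raise InvalidParameterError("w2 - w1/(w3-w2) must be positive (k12 > 0)")
    return k12, k21, ve


def _fd_derivatives(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dy = np.gradient(y, t)
    ddy = np.gradient(dy, t)
    return dy, ddy


def strong_io_residual(
    model_kind: str,
    trajectory: Trajectory,
    w: Sequence[float],
    alpha: float | None = None,
) -> np.ndarray:
    """Residual of the strong-form input-output equation on interior grid points.

    Derivatives of the observed state are estimated by second-order central
    differences, so this is a validation oracle for noiseless, densely sampled
    trajectories only.  For ``"sir"``, ``w`` is ``[beta]`` and ``alpha`` must
    be supplied; the observed I(t) must be strictly positive.
    """
    t = trajectory.times
    y = trajectory.observed
    w = np.asarray(w, dtype=float)
    if model_kind == "blood_tissue":
        dy, ddy = _fd_derivatives(y, t)
        res = (
            ddy * (1.0 + y) ** 2
            + w[0] * (y**2 + y)
            + w[1] * (dy * y**2 + 2.0 * dy * y)
            + w[2] * dy
        )
    elif model_kind == "sir":
        if alpha is None:
            raise ValueError("sir residual requires the known recovery rate alpha")
        if np.any(y <= 0):
            raise ValueError("I(t) must be positive on the grid (division by I)")
        beta = w[0]
        dy, ddy = _fd_derivatives(y, t)
        res = ddy - dy**2 / y + beta * dy * y + beta * alpha * y**2
    else:
        raise KeyError(f"unknown model kind {model_kind!r}")
    # the first/last two points carry one-sided differencing error from the
    # repeated gradient; only interior points are meaningful
    return res[2:-2]


MODEL_REGISTRY: dict[str, Callable[..., ODEModel]] = {
    "blood_tissue": make_blood_model,
    "sir": make_sir_model,
}


def make_model(kind: str, **kwargs) -> ODEModel:
    """Build a registered model by name (``"blood_tissue"`` or ``"sir"``)."""
    try:
        factory = MODEL_REGISTRY[kind]
    except KeyError:
        raise KeyError(f"unknown model kind {kind!r}; known: {sorted(MODEL_REGISTRY)}")
    return factory(**kwargs)
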