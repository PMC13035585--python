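"""Compactly supported test functions and their quadrature-weighted matrices.

Three families are provided, each supported on [-a, a], vanishing together
with enough derivatives at +-a to integrate by parts twice:

* ``bump``     — C^infinity bump  C * exp(-eta / (1 - (t/a)^2)),
* ``hartley3`` — third-order Hartley modulating function
                 C * (cas(6*pi*t/a) - 3*cas(4*pi*t/a) + 3*cas(2*pi*t/a) - 1),
                 cas(t) = cos(t) + sin(t),
* ``poly12``   — 12th-order polynomial C * (t+a)^6 * (a-t)^6.

C normalizes the continuous L2 norm on [-a, a] to 1.  Closed-form first and
second derivatives are generated symbolically (sympy) once per family and
cached, so no finite differencing of the test functions ever occurs.

``place_test_functions`` distributes K centers uniformly so every support
lies inside the observation window, and returns the K x (M+1) matrices of
phi, phi', phi'' evaluated on the grid with composite-trapezoid quadrature
weights (the order-1 Newton-Cotes rule) folded in.  These matrices are the
only interface the weak-form assembly needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.integrate import quad

__all__ = [
    "TestFunctionFamily",
    "TestFunctionGrid",
    "FAMILIES",
    "phi_and_derivatives",
    "normalization_constant",
    "place_test_functions",
    "trapezoid_weights",
]

FAMILIES = ("bump", "hartley3", "poly12")

# exclude the support boundary itself so symbolic expressions with
# (1 - (t/a)^2) denominators are never evaluated at a singular point
_EDGE = 1.0 - 1e-9


@lru_cache(maxsize=None)
def _symbolic_callables(family: str):
    t, a, eta = sp.symbols("t a eta", positive=False, real=True)
    if family == "bump":
        expr = sp.exp(-eta / (1 - (t / a) ** 2))
    elif family == "hartley3":
        cas = lambda x: sp.cos(x) + sp.sin(x)
        expr = (
            cas(6 * sp.pi * t / a)
            - 3 * cas(4 * sp.pi * t / a)
            + 3 * cas(2 * sp.pi * t / a)
            - 1
        )
    elif family == "poly12":
        expr = (t + a) ** 6 * (a - t) ** 6
    else:
        raise ValueError(f"unknown test-function family {family!r}; known: {FAMILIES}")
    return tuple(
        sp.lambdify((t, a, eta), sp.diff(expr, t, i), "numpy") for i in range(3)
    )


def _raw_phi(family: str, a: float, eta: float, t: np.ndarray, order: int) -> np.ndarray:
    """Un-normalized d^order(phi)/dt^order, zero outside the open support."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = np.abs(t) < _EDGE * a
    if np.any(inside):
        f = _symbolic_callables(family)[order]
        vals = f(t[inside], a, eta)
        out[inside] = np.broadcast_to(vals, t[inside].shape)
    return out


def normalization_constant(family: str, a: float, eta: float = 9.0) -> float:
    """C such that the continuous L2 norm of C*phi on [-a, a] equals 1."""
    if a <= 0:
        raise ValueError("support radius a must be positive")
    integrand = lambda s: _raw_phi(family, a, eta, np.array([s]), 0)[0] ** 2
    norm_sq, _ = quad(integrand, -a, a, epsabs=1e-14, epsrel=1e-12, limit=200)
    return 1.0 / np.sqrt(norm_sq)


@dataclass(frozen=True)
class TestFunctionFamily:
    """A normalized test function: family name, radius a, shape eta (bump only)."""

    __test__ = False  # not a pytest class, despite the name

    family: str
    a: float
    eta: float = 9.0
    C: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        if self.a <= 0:
            raise ValueError("support radius a must be positive")
        if self.C == 0.0:
            object.__setattr__(
                self, "C", normalization_constant(self.family, self.a, self.eta)
            )


def phi_and_derivatives(
    tf: TestFunctionFamily, t: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, phi', phi'') at offsets ``t`` from the center; zero outside [-a, a]."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return tuple(
        tf.C * _raw_phi(tf.family, tf.a, tf.eta, t, i) for i in range(3)
    )


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    """Composite trapezoid quadrature weights for an arbitrary increasing grid."""
    dt = np.diff(times)
    w = np.zeros_like(times)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return w


@dataclass(eq=False)
class TestFunctionGrid:
    """K placed test functions evaluated on the observation grid.

    ``mats[i][k, m] = (d^i phi_k / dt^i)(t_m) * q_m`` with q the trapezoid
    quadrature weights, so a weak integral of f against d^i(phi_k) is just
    ``mats[i] @ f(y)``.
    """

    __test__ = False  # not a pytest class, despite the name

    times: np.ndarray
    centers: np.ndarray
    family: TestFunctionFamily
    mats: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def K(self) -> int:
        return len(self.centers)

    def ranks(self) -> tuple[int, ...]:
        """Numerical rank of each derivative-order matrix."""
        return tuple(int(np.linalg.matrix_rank(m)) for m in self.mats)


def place_test_functions(
    times: Sequence[float],
    family: TestFunctionFamily,
    k: int | None = None,
) -> TestFunctionGrid:
    """Place K test functions with centers uniform in [T0 + a, TM - a].

    The default K is 60% of the observation count (at most 150): a large,
    overlapping set of test functions averages observation noise, while the
    margin below the data rank M+1 keeps the propagated residual covariance
    invertible.  Centers are never placed closer than half a grid step, and
    every support lies strictly inside the observation window.
    """
    times = np.asarray(times, dtype=float)
    a = family.a
    t0, tm = times[0], times[-1]
    width = tm - t0 - 2 * a
    if width <= 0:
        raise ValueError(
            f"test-function support 2a={2 * a} does not fit in the window {tm - t0}"
        )
    dt_min = float(np.min(np.diff(times)))
    k_cap = max(1, int(2 * width / dt_min) + 1)
    if k is None:
        k = min(max(int(round(0.6 * times.size)), 1), 150, k_cap)
    if k < 1:
        raise ValueError("K must be >= 1")
    k = min(k, k_cap)
    centers = np.linspace(t0 + a, tm - a, k) if k > 1 else np.array([(t0 + tm) / 2.0])
    q = trapezoid_weights(times)
    offsets = times[None, :] - centers[:, None]
    mats = tuple(
        family.C * _raw_phi(family.family, a, family.eta, offsets, i) * q[None, :]
        for i in range(3)
    )
    return TestFunctionGrid(times=times, centers=centers, family=family, mats=mats)
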