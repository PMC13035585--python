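"""Weak-form input-output linear systems and the WENDy-style solver.

An input-output equation in a single observed state y can be written as a
sum of terms d^i/dt^i [ f(y) ], linear in the unknown coefficient vector w.
Integrating against a compactly supported test function phi and moving the
derivatives onto phi by parts yields, for each placed test function, one
linear equation in w with data-dependent coefficients:

    sum_i (-1)^(i+1) int (d^i phi) H_i(y) dt
        = [ sum_i (-1)^i int (d^i phi) C_i(y) dt ] w

Discretizing the integrals with quadrature on the observation grid gives a
K x n linear system G w ~ b (one row per test function).

Because the same noisy data enter both G and b, ordinary least squares is
biased at larger noise (an errors-in-variables problem).  The solver
therefore iterates generalized least squares: at the current iterate w, the
residual r = b - G w is linearized in the observation errors,
r ~ r* + L(w) eps, with L assembled from the analytic derivatives of the
H_i/C_i terms with respect to y composed with the test-function matrices.
The working covariance L L^T then whitens the next solve, and the
parameter covariance (G^T (L L^T)^{-1} G)^{-1}, scaled by a residual-based
noise variance estimate, yields Wald confidence intervals.

For multiplicative lognormal noise, first-order propagation gives
delta y ~ y * eta with eta the log-errors, so L is scaled columnwise by the
observed data before forming the covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm

from .noise import MULTIPLICATIVE, ObservationSet
from .test_functions import TestFunctionGrid

__all__ = [
    "WeakTerm",
    "WeakIOSystem",
    "LinearSystem",
    "WENDyFit",
    "RankDiagnostics",
    "AssemblyError",
    "NonIdentifiableError",
    "build_weak_blood_system",
    "build_weak_sir_system",
    "cumulative_trapezoid_matrix",
    "assemble",
    "wendy_solve",
    "confidence_intervals",
    "check_rank",
]


class AssemblyError(RuntimeError):
    """A weak-form term evaluated to a non-finite value."""


class NonIdentifiableError(RuntimeError):
    """G is rank deficient: the weak regression has no unique solution."""

    def __init__(self, message: str, rank_g: int):
        super().__init__(message)
        self.rank_g = rank_g


@dataclass(eq=False)
class WeakTerm:
    """One term d^i/dt^i [ func(y) ] of a weak-form equation side.

    ``func(y, times)`` returns the integrand sampled on the grid;
    ``jac(y, times)`` returns its derivative with respect to the data — a
    vector for pointwise (diagonal) terms, or a full (M+1, M+1) matrix for
    terms with memory such as a cumulative integral.
    """

    order: int
    name: str
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    jac: Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(eq=False)
class WeakIOSystem:
    """A weak-form input-output equation: b-side terms and one term list per unknown."""

    name: str
    w_names: tuple[str, ...]
    terms_b: list[WeakTerm]
    terms_g: list[list[WeakTerm]]
    known_params: dict[str, float] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.w_names)


@dataclass(eq=False)
class LinearSystem:
    """Discretized weak system G w ~ b with one row per test function."""

    G: np.ndarray
    b: np.ndarray
    system_name: str
    K: int

    @property
    def degenerate(self) -> bool:
        return not (np.any(self.G) or np.any(self.b))


@dataclass(eq=False)
class WENDyFit:
    """Result of one weak-form fit."""

    w_hat: np.ndarray
    covariance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    iterations: int
    converged: bool
    rank_g: int
    sigma_hat: float
    level: float = 0.95


@dataclass(frozen=True)
class RankDiagnostics:
    """Numerical ranks of G and of each test-function derivative matrix."""

    rank_g: int
    n_params: int
    phi_ranks: tuple[int, ...]
    K: int

    @property
    def identifiable(self) -> bool:
        return self.rank_g == self.n_params


def build_weak_blood_system() -> WeakIOSystem:
    """Weak input-output equation of the blood-tissue model (observed x1).

        -int phi'' x1 = w1 int phi x1/(x1+1) - w2 int phi' x1^2/(x1+1)
                        + w3 int phi' 1/(x1+1)

    Encoded in the generic sign convention: b-side terms carry (-1)^(i+1),
    G-side terms carry (-1)^i, applied during assembly.
    """
    b_terms = [
        WeakTerm(2, "x1", lambda y, t: y, lambda y, t: np.ones_like(y)),
    ]
    g_terms = [
        [WeakTerm(0, "x1/(1+x1)", lambda y, t: y / (1 + y),
                  lambda y, t: 1.0 / (1 + y) ** 2)],
        [WeakTerm(1, "x1^2/(1+x1)", lambda y, t: y**2 / (1 + y),
                  lambda y, t: (y**2 + 2 * y) / (1 + y) ** 2)],
        [WeakTerm(1, "-1/(1+x1)", lambda y, t: -1.0 / (1 + y),
                  lambda y, t: 1.0 / (1 + y) ** 2)],
    ]
    return WeakIOSystem(
        name="blood_tissue",
        w_names=("w1", "w2", "w3"),
        terms_b=b_terms,
        terms_g=g_terms,
    )


def cumulative_trapezoid_matrix(times: np.ndarray) -> np.ndarray:
    """Lower-triangular matrix L with (L @ f)[m] = trapezoid integral of f on [t0, tm]."""
    times = np.asarray(times, dtype=float)
    m = times.size
    dt = np.diff(times)
    L = np.zeros((m, m))
    for i in range(1, m):
        L[i] = L[i - 1]
        L[i, i - 1] += dt[i - 1] / 2.0
        L[i, i] += dt[i - 1] / 2.0
    return L


def build_weak_sir_system(alpha_known: float, s0: float) -> WeakIOSystem:
    """Weak SIR equation for the transmission rate beta with alpha known.

        -int phi' I + alpha int phi I = -beta int phi (R(t) + I - S0) I,
        R(t) = alpha * cumulative trapezoid of I(t).

    This is the weak form of I' = beta*S*I - alpha*I after substituting
    S = N - I - R and integrating the I' term by parts (int phi I' dt =
    -int phi' I dt for compactly supported phi).  The recovered compartment
    R is reconstructed from the noisy observed I, so the beta column has a
    dense (cumulative-integral) data Jacobian.
    """
    if alpha_known <= 0:
        raise ValueError("alpha_known must be positive")
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    a = float(alpha_known)
    s0 = float(s0)

    def g_func(y: np.ndarray, t: np.ndarray) -> np.ndarray:
        r = a * (cumulative_trapezoid_matrix(t) @ y)
        return -(r + y - s0) * y

    def g_jac(y: np.ndarray, t: np.ndarray) -> np.ndarray:
        L = cumulative_trapezoid_matrix(t)
        r = a * (L @ y)
        return -(np.diag(r + 2 * y - s0) + y[:, None] * (a * L))

    b_terms = [
        WeakTerm(1, "-I", lambda y, t: -y, lambda y, t: -np.ones_like(y)),
        WeakTerm(0, "-alpha*I", lambda y, t: -a * y,
                 lambda y, t: -a * np.ones_like(y)),
    ]
    g_terms = [[WeakTerm(0, "-(R+I-S0)*I", g_func, g_jac)]]
    return WeakIOSystem(
        name="sir",
        w_names=("beta",),
        terms_b=b_terms,
        terms_g=g_terms,
        known_params={"alpha": a, "S0": s0},
    )


def _apply_term(term: WeakTerm, sign: float, tf: TestFunctionGrid,
                y: np.ndarray, t: np.ndarray) -> np.ndarray:
    vals = term.func(y, t)
    if not np.all(np.isfinite(vals)):
        raise AssemblyError(f"term {term.name!r} evaluated to non-finite values")
    return sign * (tf.mats[term.order] @ vals)


def assemble(system: WeakIOSystem, obs: ObservationSet,
             tf: TestFunctionGrid) -> LinearSystem:
    """Build the K x n linear system G w ~ b from one noisy observation set."""
    if obs.times.size != tf.times.size or not np.allclose(obs.times, tf.times):
        raise ValueError("observation grid and test-function grid must agree")
    y, t = obs.y, obs.times
    k = tf.K
    b = np.zeros(k)
    for term in system.terms_b:
        b += _apply_term(term, (-1.0) ** (term.order + 1), tf, y, t)
    G = np.zeros((k, system.n_params))
    for j, terms in enumerate(system.terms_g):
        for term in terms:
            G[:, j] += _apply_term(term, (-1.0) ** term.order, tf, y, t)
    return LinearSystem(G=G, b=b, system_name=system.name, K=k)


def _residual_jacobian(system: WeakIOSystem, w: np.ndarray, y: np.ndarray,
                       t: np.ndarray, tf: TestFunctionGrid,
                       lognormal: bool) -> np.ndarray:
    """L = d(b - G w)/dy, the first-order noise-propagation operator."""

    def term_jac(term: WeakTerm, sign: float) -> np.ndarray:
        d = term.jac(y, t)
        mat = tf.mats[term.order]
        if d.ndim == 1:  # pointwise term: diagonal Jacobian
            return sign * (mat * d[None, :])
        return sign * (mat @ d)

    L = np.zeros((tf.K, y.size))
    for term in system.terms_b:
        L += term_jac(term, (-1.0) ** (term.order + 1))
    for j, terms in enumerate(system.terms_g):
        for term in terms:
            L -= w[j] * term_jac(term, (-1.0) ** term.order)
    if lognormal:
        # delta y ~ y * eta to first order in the log-errors eta
        L = L * y[None, :]
    return L


def wendy_solve(
    ls: LinearSystem,
    system: WeakIOSystem,
    obs: ObservationSet,
    tf: TestFunctionGrid,
    sigma: float | None = None,
    level: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> WENDyFit:
    """Iteratively reweighted weak-form regression with Wald intervals.

    Step 0 is ordinary least squares; each subsequent step whitens with the
    covariance L L^T propagated from the observation noise at the current
    iterate and re-solves, until the relative change in w falls below
    ``tol`` or ``max_iter`` reweighting steps have run.  When ``sigma`` is
    not supplied the noise scale is estimated from the whitened residuals.
    """
    G, b = ls.G, ls.b
    n = system.n_params
    rank_g = int(np.linalg.matrix_rank(G))
    if rank_g < n:
        raise NonIdentifiableError(
            f"rank(G)={rank_g} < n={n}: weak system is not locally identifiable",
            rank_g,
        )
    lognormal = obs.spec.kind == MULTIPLICATIVE
    w = np.linalg.lstsq(G, b, rcond=None)[0]
    gw, bw = G, b  # whitened copies from the last successful weighting
    iterations = 0
    converged = True
    # floor on the covariance spectrum, relative to its largest eigenvalue:
    # keeps the whitening bounded where L L^T is (numerically) rank deficient
    eig_floor = 1e-10
    for it in range(1, max_iter + 1):
        L = _residual_jacobian(system, w, obs.y, obs.times, tf, lognormal)
        S = L @ L.T
        lam, v = np.linalg.eigh(S)
        lam_max = max(lam[-1], 1e-300)
        lam = np.maximum(lam, eig_floor * lam_max)
        whiten = (v / np.sqrt(lam)[None, :]) @ v.T
        gw = whiten @ G
        bw = whiten @ b
        w_new = np.linalg.lstsq(gw, bw, rcond=None)[0]
        iterations = it
        step = np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-300)
        w = w_new
        if step < tol:
            break
    else:
        converged = False

    resid = bw - gw @ w
    dof = max(ls.K - n, 1)
    sigma_hat = float(sigma) if sigma is not None else float(
        np.sqrt(resid @ resid / dof)
    )
    gtg = gw.T @ gw
    cov = sigma_hat**2 * np.linalg.inv(gtg)
    cov = (cov + cov.T) / 2.0
    fit = WENDyFit(
        w_hat=w,
        covariance=cov,
        ci_low=np.empty(n),
        ci_high=np.empty(n),
        iterations=iterations,
        converged=converged,
        rank_g=rank_g,
        sigma_hat=sigma_hat,
        level=level,
    )
    return confidence_intervals(fit, level)


def confidence_intervals(fit: WENDyFit, level: float = 0.95) -> WENDyFit:
    """Attach normal-theory (Wald) intervals w_hat +- z * sqrt(cov_ii)."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    se = np.sqrt(np.clip(np.diag(fit.covariance), 0.0, None))
    fit.ci_low = fit.w_hat - z * se
    fit.ci_high = fit.w_hat + z * se
    fit.level = level
    return fit


def check_rank(ls: LinearSystem, tf: TestFunctionGrid) -> RankDiagnostics:
    """Local-identifiability diagnostics: rank(G) and rank of each Phi matrix."""
    n = ls.G.shape[1]
    return RankDiagnostics(
        rank_g=int(np.linalg.matrix_rank(ls.G)),
        n_params=n,
        phi_ranks=tf.ranks(),
        K=tf.K,
    )
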