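"""Monte-Carlo practical-identifiability summaries and (e,q) maps.

For an ensemble of D noisy datasets at observation error ratio e, the
weak-form estimator is applied to each replicate and summarized per
parameter by MSE (against the true coefficient vector w*), bias, variance,
average relative error, and the empirical coverage of the nominal 95%
confidence intervals.

The (e,q)-identifiability criterion: the model is (e,q)-identifiable when
sqrt(MSE_i) <= q * |w_i| for every parameter i, i.e. the estimator error
ratio max_i sqrt(MSE_i)/|w_i| is at most q.  ``eq_grid`` fills the boolean
(e x q) map from Monte-Carlo summaries, and ``parameter_sweep`` maps the
minimum satisfied q over a grid of blood-model coefficient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ExperimentConfig, build_experiment
from .models import invert_coefficient_map_blood, InvalidParameterError
from .noise import NoiseSpec, ObservationSet, generate_ensemble
from .weak_wendy import (
    NonIdentifiableError,
    WENDyFit,
    WeakIOSystem,
    assemble,
    wendy_solve,
)
from .test_functions import TestFunctionGrid

__all__ = [
    "ReplicateSummary",
    "EQGrid",
    "fit_ensemble",
    "summaries_for_e_values",
    "summarize",
    "is_eq_identifiable",
    "min_q",
    "eq_grid",
    "parameter_sweep",
]


class SummaryError(RuntimeError):
    """No successful fits to summarize."""


@dataclass(eq=False)
class ReplicateSummary:
    """Per-parameter Monte-Carlo statistics of one (model, e) ensemble."""

    e: float
    w_true: np.ndarray
    w_names: tuple[str, ...]
    d: int
    failures: int
    mean_est: np.ndarray
    bias: np.ndarray
    variance: np.ndarray
    mse: np.ndarray
    relative_error: np.ndarray      # mean over replicates of |w_hat - w*|/|w*|
    coverage: np.ndarray            # fraction of CIs containing w*

    @property
    def avg_relative_error(self) -> float:
        """Relative error additionally averaged over parameters."""
        return float(np.mean(self.relative_error))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "e": self.e,
                "parameter": list(self.w_names),
                "w_true": self.w_true,
                "mean_est": self.mean_est,
                "bias": self.bias,
                "variance": self.variance,
                "mse": self.mse,
                "relative_error": self.relative_error,
                "coverage": self.coverage,
                "D": self.d,
                "failures": self.failures,
            }
        )


@dataclass(eq=False)
class EQGrid:
    """Boolean (e,q)-identifiability map with the per-e minimum satisfied q."""

    e_values: np.ndarray
    q_values: np.ndarray
    identifiable: np.ndarray          # shape (len(e), len(q)), bool
    min_q: np.ndarray                 # per e: max_i sqrt(MSE_i)/|w_i|
    summaries: list[ReplicateSummary] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.identifiable.astype(int),
            index=pd.Index(self.e_values, name="e"),
            columns=pd.Index(self.q_values, name="q"),
        )


def fit_ensemble(
    system: WeakIOSystem,
    ensemble: Sequence[ObservationSet],
    tf: TestFunctionGrid,
    sigma: float | None = None,
) -> list[WENDyFit | None]:
    """WENDy fit of every replicate; failed fits are returned as None."""
    fits: list[WENDyFit | None] = []
    for obs in ensemble:
        try:
            ls = assemble(system, obs, tf)
            fits.append(wendy_solve(ls, system, obs, tf, sigma=sigma))
        except (NonIdentifiableError, np.linalg.LinAlgError, RuntimeError):
            fits.append(None)
    return fits


def summarize(
    fits: Sequence[WENDyFit | None],
    w_true: Sequence[float],
    e: float,
    w_names: Sequence[str] | None = None,
) -> ReplicateSummary:
    """Collapse an ensemble of fits into per-parameter Monte-Carlo statistics."""
    w_true = np.asarray(w_true, dtype=float)
    if np.any(w_true == 0):
        raise ValueError("w_true must be nonzero componentwise")
    good = [f for f in fits if f is not None and np.all(np.isfinite(f.w_hat))]
    failures = len(fits) - len(good)
    if not good:
        raise SummaryError("all fits in the ensemble failed")
    w_hat = np.array([f.w_hat for f in good])
    lo = np.array([f.ci_low for f in good])
    hi = np.array([f.ci_high for f in good])
    err = w_hat - w_true[None, :]
    mean_est = w_hat.mean(axis=0)
    bias = mean_est - w_true
    variance = w_hat.var(axis=0)
    mse = np.mean(err**2, axis=0)
    rel = np.mean(np.abs(err) / np.abs(w_true)[None, :], axis=0)
    cover = np.mean((lo <= w_true[None, :]) & (w_true[None, :] <= hi), axis=0)
    names = tuple(w_names) if w_names is not None else tuple(
        f"w{i + 1}" for i in range(w_true.size)
    )
    return ReplicateSummary(
        e=float(e),
        w_true=w_true,
        w_names=names,
        d=len(fits),
        failures=failures,
        mean_est=mean_est,
        bias=bias,
        variance=variance,
        mse=mse,
        relative_error=rel,
        coverage=cover,
    )


def min_q(summary: ReplicateSummary) -> float:
    """Smallest q satisfying the criterion: max_i sqrt(MSE_i)/|w_i|."""
    return float(np.max(np.sqrt(summary.mse) / np.abs(summary.w_true)))


def is_eq_identifiable(summary: ReplicateSummary, q: float) -> bool:
    """True iff sqrt(MSE_i) <= q*|w_i| for every parameter."""
    if q <= 0:
        raise ValueError("q must be positive")
    return min_q(summary) <= q


def summaries_for_e_values(
    config: ExperimentConfig,
    e_values: Sequence[float],
    d: int,
    seed: int,
) -> list[ReplicateSummary]:
    model, system, times, truth, tf, w_true = build_experiment(config)
    out = []
    for idx, e in enumerate(e_values):
        spec = NoiseSpec(kind=config.noise_kind, e=float(e),
                         seed=(seed + 100_003 * idx) % 2**31)
        ensemble = generate_ensemble(model, times, spec, d, truth=truth)
        fits = fit_ensemble(system, ensemble, tf)
        out.append(summarize(fits, w_true, e, w_names=system.w_names))
    return out


def eq_grid(
    config: ExperimentConfig,
    e_values: Sequence[float] | None = None,
    q_values: Sequence[float] | None = None,
    d: int | None = None,
    seed: int | None = None,
) -> EQGrid:
    """Monte-Carlo (e,q)-identifiability map for one experiment configuration.

    Runs ensemble generation, WENDy fitting and summarization at each e and
    marks cell (e, q) identifiable when the per-e minimum satisfied q is at
    most q.  Each row is therefore monotone nondecreasing in q by
    construction.
    """
    e_values = np.asarray(
        config.e_values if e_values is None else e_values, dtype=float
    )
    q_values = np.asarray(
        config.q_values if q_values is None else q_values, dtype=float
    )
    if e_values.size == 0 or q_values.size == 0:
        raise ValueError("e and q grids must be nonempty")
    d = config.d if d is None else d
    seed = config.seed if seed is None else seed
    summaries = summaries_for_e_values(config, e_values, d, seed)
    mq = np.array([min_q(s) for s in summaries])
    identifiable = mq[:, None] <= q_values[None, :]
    return EQGrid(
        e_values=e_values,
        q_values=q_values,
        identifiable=identifiable,
        min_q=mq,
        summaries=summaries,
    )


def parameter_sweep(
    w2_range: Sequence[float],
    w3_range: Sequence[float],
    w1_fixed: float,
    e_values: Sequence[float],
    d: int = 1000,
    seed: int = 0,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """min_q over a grid of blood-model coefficient vectors (w1 fixed).

    Each feasible (w1, w2, w3) is inverted to mechanistic rates
    (k12, k21, Ve); infeasible cells (Ve <= 0 or k12 <= 0) are flagged and
    skipped.  Returns a long-format frame with one row per (cell, e).
    """
    from .config import blood_config  # local import to avoid cycles in doc order

    base = config if config is not None else blood_config()
    rows = []
    for w2 in w2_range:
        for w3 in w3_range:
            try:
                k12, k21, ve = invert_coefficient_map_blood(w1_fixed, w2, w3)
                feasible = True
            except InvalidParameterError:
                feasible = False
            if not feasible:
                for e in e_values:
                    rows.append(
                        dict(w1=w1_fixed, w2=w2, w3=w3, e=e, feasible=False,
                             min_q=np.nan)
                    )
                continue
            cell_cfg = base.replace(
                model_params={"k12": k12, "k21": k21, "ve": ve, "ic": base.model_params.get("ic", (1.0, 0.0))}
            )
            summaries = summaries_for_e_values(cell_cfg, e_values, d, seed)
            for e, s in zip(e_values, summaries):
                rows.append(
                    dict(w1=w1_fixed, w2=w2, w3=w3, e=e, feasible=True,
                         min_q=min_q(s))
                )
    return pd.DataFrame(rows)
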