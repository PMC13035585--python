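"""Weak-form system assembly and the iteratively reweighted solver:
noiseless recovery, refinement convergence, rank diagnostics, intervals."""

import numpy as np
import pytest

from weakident.config import blood_config, sir_config, build_experiment
from weakident.models import Trajectory, make_blood_model, make_sir_model, simulate
from weakident.noise import ADDITIVE, NoiseSpec, ObservationSet, apply_noise
from weakident.test_functions import TestFunctionFamily, place_test_functions
from weakident.weak_wendy import (
    AssemblyError,
    NonIdentifiableError,
    WENDyFit,
    assemble,
    build_weak_blood_system,
    build_weak_sir_system,
    check_rank,
    confidence_intervals,
    cumulative_trapezoid_matrix,
    wendy_solve,
)


def noiseless_obs(truth, times):
    return apply_noise(truth, times, NoiseSpec(ADDITIVE, 0.0, seed=0))


class TestBloodSystem:
    def test_structure(self, blood_experiment):
        _, system, _, _, tf, _ = blood_experiment
        assert system.w_names == ("w1", "w2", "w3")
        assert system.n_params == 3

    def test_shapes(self, blood_experiment):
        _, system, times, truth, tf, _ = blood_experiment
        ls = assemble(system, noiseless_obs(truth.observed, times), tf)
        assert ls.G.shape == (tf.K, 3)
        assert ls.b.shape == (tf.K,)

    def test_zero_signal_degenerates(self, blood_experiment):
        _, system, times, _, tf, _ = blood_experiment
        obs = noiseless_obs(np.zeros_like(times), times)
        ls = assemble(system, obs, tf)
        # x1 == 0 kills the w1/w2 columns; the w3 column is a quadrature of
        # phi', which integrates to zero over each compact support
        np.testing.assert_allclose(ls.G[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(ls.G[:, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(ls.G[:, 2], 0.0, atol=1e-3)

    def test_b_side_linear_in_data(self, blood_experiment):
        _, system, times, truth, tf, _ = blood_experiment
        b1 = assemble(system, noiseless_obs(truth.observed, times), tf).b
        b2 = assemble(system, noiseless_obs(2 * truth.observed, times), tf).b
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-12)

    def test_weak_residual_shrinks_under_refinement(self):
        # noiseless data at the true coefficients: || b - G w* || / ||b||
        # decreases as the observation grid refines
        rels = []
        for n in (100, 400):
            cfg = blood_config(n_obs=n)
            _, system, times, truth, tf, w_true = build_experiment(cfg)
            ls = assemble(system, noiseless_obs(truth.observed, times), tf)
            rels.append(
                np.linalg.norm(ls.b - ls.G @ w_true) / np.linalg.norm(ls.b)
            )
        assert rels[1] < rels[0] < 1e-2

    def test_non_finite_term_raises(self, blood_experiment):
        _, system, times, _, tf, _ = blood_experiment
        y = np.full_like(times, -1.0)  # 1/(1+x1) blows up
        with pytest.raises(AssemblyError):
            assemble(system, noiseless_obs(y, times), tf)

    def test_grid_mismatch_rejected(self, blood_experiment):
        _, system, times, truth, tf, _ = blood_experiment
        other = np.linspace(0, 2, times.size + 1)
        with pytest.raises(ValueError):
            assemble(system, noiseless_obs(np.ones_like(other), other), tf)


class TestSIRSystem:
    def test_single_unknown(self, sir_experiment):
        _, system, _, _, _, _ = sir_experiment
        assert system.w_names == ("beta",)

    def test_zero_infection_degenerate(self, sir_experiment):
        _, system, times, _, tf, _ = sir_experiment
        ls = assemble(system, noiseless_obs(np.zeros_like(times), times), tf)
        assert ls.degenerate
        with pytest.raises(NonIdentifiableError):
            wendy_solve(ls, system, noiseless_obs(np.zeros_like(times), times),
                        tf, sigma=1.0)

    def test_cumulative_trapezoid_matrix(self):
        t = np.linspace(0, 1, 51)
        f = np.exp(t)
        from scipy.integrate import cumulative_trapezoid

        expected = np.concatenate([[0.0], cumulative_trapezoid(f, t)])
        np.testing.assert_allclose(cumulative_trapezoid_matrix(t) @ f, expected)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            build_weak_sir_system(alpha_known=0.0, s0=9999)
        with pytest.raises(ValueError):
            build_weak_sir_system(alpha_known=5.0, s0=-1)


class TestNoiselessRecovery:
    def test_blood_coefficients(self, blood_experiment_dense):
        _, system, times, truth, tf, w_true = blood_experiment_dense
        obs = noiseless_obs(truth.observed, times)
        fit = wendy_solve(assemble(system, obs, tf), system, obs, tf)
        np.testing.assert_allclose(fit.w_hat, [6.0, 6.0, 12.0], rtol=1e-3)
        assert fit.converged

    def test_blood_refinement_convergence(self):
        errs = []
        for n in (100, 400):
            _, system, times, truth, tf, w_true = build_experiment(
                blood_config(n_obs=n)
            )
            obs = noiseless_obs(truth.observed, times)
            fit = wendy_solve(assemble(system, obs, tf), system, obs, tf)
            errs.append(np.max(np.abs(fit.w_hat - w_true) / w_true))
        assert errs[1] < errs[0]

    def test_sir_beta(self, sir_experiment):
        _, system, times, truth, tf, w_true = sir_experiment
        obs = noiseless_obs(truth.observed, times)
        fit = wendy_solve(assemble(system, obs, tf), system, obs, tf)
        assert fit.w_hat[0] == pytest.approx(5.5e-4, rel=1e-3)

    def test_noiseless_matches_ols(self, sir_experiment):
        _, system, times, truth, tf, _ = sir_experiment
        obs = noiseless_obs(truth.observed, times)
        ls = assemble(system, obs, tf)
        ols = np.linalg.lstsq(ls.G, ls.b, rcond=None)[0]
        fit = wendy_solve(ls, system, obs, tf)
        # residual is pure quadrature error, so OLS and GLS agree only to
        # quadrature tolerance
        np.testing.assert_allclose(fit.w_hat, ols, rtol=1e-3)


class TestRankDiagnostics:
    def test_default_blood_rank(self, blood_experiment):
        _, system, times, truth, tf, _ = blood_experiment
        ls = assemble(system, noiseless_obs(truth.observed, times), tf)
        diag = check_rank(ls, tf)
        assert diag.rank_g == 3
        assert diag.identifiable
        assert diag.phi_ranks == (tf.K, tf.K, tf.K)

    def test_k1_blood_not_identifiable(self):
        cfg = blood_config()
        model, system, times, truth, _, _ = build_experiment(cfg)
        tf1 = place_test_functions(times, TestFunctionFamily("poly12", 0.52), 1)
        obs = noiseless_obs(truth.observed, times)
        ls = assemble(system, obs, tf1)
        diag = check_rank(ls, tf1)
        assert diag.rank_g <= 1 and not diag.identifiable
        with pytest.raises(NonIdentifiableError) as err:
            wendy_solve(ls, system, obs, tf1)
        assert err.value.rank_g <= 1

    def test_k1_sir_still_solvable(self, sir_experiment):
        # a single test function suffices for the one-parameter SIR system
        model, system, times, truth, _, w_true = sir_experiment
        fam = TestFunctionFamily("poly12", 7.5)
        tf1 = place_test_functions(times, fam, 1)
        obs = noiseless_obs(truth.observed, times)
        fit = wendy_solve(assemble(system, obs, tf1), system, obs, tf1)
        assert fit.w_hat[0] == pytest.approx(w_true[0], rel=0.05)


class TestConfidenceIntervals:
    def test_level_validation(self):
        fit = WENDyFit(np.zeros(1), np.eye(1), np.zeros(1), np.zeros(1), 1, True, 1, 1.0)
        with pytest.raises(ValueError):
            confidence_intervals(fit, 1.5)

    def test_degenerate_interval(self):
        fit = WENDyFit(np.array([2.0]), np.zeros((1, 1)), np.zeros(1),
                       np.zeros(1), 1, True, 1, 0.0)
        fit = confidence_intervals(fit, 0.95)
        assert fit.ci_low[0] == fit.ci_high[0] == 2.0

    def test_width_scales_with_sd(self):
        for var, ref in [(1.0, None), (4.0, 2.0)]:
            fit = WENDyFit(np.array([0.0]), np.array([[var]]), np.zeros(1),
                           np.zeros(1), 1, True, 1, 1.0)
            fit = confidence_intervals(fit, 0.95)
            width = fit.ci_high[0] - fit.ci_low[0]
            if ref is None:
                base = width
            else:
                assert width == pytest.approx(ref * base)

    def test_wald_coverage_on_gaussian_toy(self):
        # estimates drawn from the very normal model the intervals assume
        rng = np.random.default_rng(1)
        sd, n = 0.7, 2000
        hits = 0
        for _ in range(n):
            w_hat = np.array([1.0 + sd * rng.standard_normal()])
            fit = WENDyFit(w_hat, np.array([[sd**2]]), np.zeros(1),
                           np.zeros(1), 1, True, 1, sd)
            fit = confidence_intervals(fit, 0.95)
            hits += fit.ci_low[0] <= 1.0 <= fit.ci_high[0]
        assert hits / n == pytest.approx(0.95, abs=0.02)


class TestReweighting:
    def test_reweighting_keeps_noiseless_fixed_point(self, blood_experiment_dense):
        # with no noise the GLS iteration must not drift from the OLS optimum
        # beyond quadrature tolerance, and must terminate quickly
        _, system, times, truth, tf, w_true = blood_experiment_dense
        obs = noiseless_obs(truth.observed, times)
        ls = assemble(system, obs, tf)
        ols = np.linalg.lstsq(ls.G, ls.b, rcond=None)[0]
        fit = wendy_solve(ls, system, obs, tf)
        np.testing.assert_allclose(fit.w_hat, ols, rtol=1e-3)
        assert fit.converged and fit.iterations <= 5

    def test_covariance_symmetric_psd(self, sir_experiment):
        _, system, times, truth, tf, _ = sir_experiment
        obs = apply_noise(truth.observed, times, NoiseSpec(ADDITIVE, 0.5, 3))
        fit = wendy_solve(assemble(system, obs, tf), system, obs, tf)
        np.testing.assert_allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) >= -1e-12)
        assert np.all(fit.ci_low <= fit.w_hat) and np.all(fit.w_hat <= fit.ci_high)
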