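"""Potential/gradient correctness, Langevin sampling against known
targets, WAIC/WBIC estimator oracles, and Bayes-factor arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphlda.bayes import (BayesianRegressor, LMCConfig, RegressionTask,
                            bayes_factor_2log, evaluate_representation,
                            kass_raftery_label, lmc_sample, potential, waic,
                            wbic)
from graphlda.fixtures import gen_conjugate_regression


class TestPotential:
    def test_constant_predictor_closed_form(self):
        # bias-only model on zero features: prediction is the scalar w[d]
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        task = RegressionTask(np.zeros((20, 1)), y, noise=0.7)
        reg = BayesianRegressor(1, architecture="linear", tau=2.0)
        w = np.array([0.0, 0.3])  # slope (unused), bias c = 0.3
        val, _ = potential(w, task, reg)
        nll = (0.5 * ((y - 0.3) ** 2).sum() / 0.49
               + 20 * 0.5 * np.log(2 * np.pi * 0.49))
        prior = (0.5 * (w ** 2).sum() / 4.0
                 + 2 * 0.5 * np.log(2 * np.pi * 4.0))
        assert val == pytest.approx(nll + prior, rel=1e-12)

    @pytest.mark.parametrize("arch", ["linear", "mlp"])
    def test_gradient_matches_finite_differences(self, arch):
        rng = np.random.default_rng(1)
        task = RegressionTask(rng.normal(size=(15, 3)),
                              rng.normal(size=15), noise=0.5)
        reg = BayesianRegressor(3, architecture=arch, hidden=8)
        for seed in range(10):
            w = np.random.default_rng(seed).normal(size=reg.n_params)
            _, grad = potential(w, task, reg, beta=0.7)
            eps = 1e-6
            num = np.zeros_like(w)
            for i in range(len(w)):
                wp, wm = w.copy(), w.copy()
                wp[i] += eps
                wm[i] -= eps
                num[i] = (potential(wp, task, reg, beta=0.7)[0]
                          - potential(wm, task, reg, beta=0.7)[0]) / (2 * eps)
            denom = np.maximum(np.abs(num), 1.0)
            assert np.max(np.abs(grad - num) / denom) < 1e-5

    def test_beta_zero_rejected(self):
        task = RegressionTask(np.zeros((5, 1)), np.zeros(5), noise=1.0)
        reg = BayesianRegressor(1, architecture="linear")
        with pytest.raises(ValueError):
            potential(np.zeros(reg.n_params), task, reg, beta=0.0)


class TestLMC:
    def test_standard_normal_target(self):
        # U = ||w||^2/2: stationary distribution N(0, I) up to O(eta^2) bias
        def U(w):
            return 0.5 * float(w @ w), w.copy()

        cfg = LMCConfig(step=0.2, n_iterations=100_000, burn_in=5_000,
                        thinning=5, seed=0, init_scale=1.0)
        W = lmc_sample(U, 3, cfg)
        assert np.all(W.var(axis=0) > 0.9)
        assert np.all(W.var(axis=0) < 1.1)

    def test_conjugate_posterior_mean(self):
        data = gen_conjugate_regression(n=100, p=3, noise=0.5, seed=2)
        task = RegressionTask(data.X, data.y, data.noise)
        reg = BayesianRegressor(3, architecture="linear", tau=data.tau,
                                bias=False)
        cfg = LMCConfig(step=3e-3, n_iterations=60_000, burn_in=10_000,
                        thinning=10, seed=3)
        W = lmc_sample(lambda w: potential(w, task, reg), reg.n_params, cfg)
        post_sd = np.sqrt(np.diag(data.post_cov))
        # generous effective-sample allowance for chain autocorrelation
        se = 3 * post_sd / np.sqrt(len(W) / 20)
        assert np.all(np.abs(W.mean(axis=0) - data.post_mean) < 3 * se)

    def test_same_seed_same_chain(self):
        def U(w):
            return 0.5 * float(w @ w), w.copy()

        cfg = LMCConfig(step=0.1, n_iterations=2_000, burn_in=100,
                        thinning=10, seed=9)
        assert np.array_equal(lmc_sample(U, 2, cfg), lmc_sample(U, 2, cfg))

    def test_divergence_guard(self):
        def U(w):  # anti-gradient: pushes w to infinity
            return 0.0, -w * 1e3

        cfg = LMCConfig(step=1.0, n_iterations=10_000, burn_in=100,
                        thinning=1, seed=0, init_scale=10.0)
        with pytest.raises(FloatingPointError, match="step"):
            lmc_sample(U, 2, cfg)


class TestWAIC:
    def test_concentrated_posterior(self):
        row = np.array([-1.0, -2.0, -0.5])
        ll = np.tile(row, (50, 1))
        assert waic(ll) == pytest.approx(-row.mean())

    def test_toy_matrix_brute_force(self):
        ll = np.array([[-1.0, -2.0], [-3.0, -2.0]])
        # direct evaluation of the defining formula
        lppd = np.log(np.mean(np.exp(ll), axis=0))
        penalty = np.mean(ll ** 2, axis=0) - np.mean(ll, axis=0) ** 2
        expected = float(np.mean(-lppd + penalty))
        assert waic(ll) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        ll = rng.normal(-2, 1, size=(rng.integers(2, 30),
                                     rng.integers(1, 20)))
        lppd = np.log(np.mean(np.exp(ll), axis=0))
        penalty = ll.var(axis=0)
        assert waic(ll) == pytest.approx(float(np.mean(-lppd + penalty)),
                                         rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            waic(np.zeros((1, 5)))
        with pytest.raises(FloatingPointError):
            waic(np.array([[0.0, np.inf], [0.0, 0.0]]))


class TestWBIC:
    def test_concentrated_posterior(self):
        row = np.array([-1.5, -0.5, -2.0])
        ll = np.tile(row, (30, 1))
        assert wbic(ll) == pytest.approx(-row.sum())

    def test_model_selection_smoke(self):
        # data from a 1-feature model: a 5-feature model (4 junk features)
        # should pay a complexity penalty in WBIC
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 1000
            x = rng.normal(size=(n, 1))
            y = 1.2 * x[:, 0] + 0.5 * rng.normal(size=n)
            junk = rng.normal(size=(n, 4))
            beta = 1 / np.log(n)
            wbics = []
            for X in (x, np.hstack([x, junk])):
                from graphlda.fixtures import ConjugateRegression

                data = ConjugateRegression(X, y, np.zeros(X.shape[1]),
                                           noise=0.5, tau=1.0)
                W = data.sample_posterior(500, seed=rep, beta=beta)
                wbics.append(wbic(data.loglik_matrix(W)))
            wins += wbics[1] > wbics[0]
        assert wins > 10


class TestBayesFactor:
    def test_published_comparisons(self):
        # free energies of two encoder models on the same task
        assert bayes_factor_2log(843.67, 852.15) == pytest.approx(16.96)
        assert bayes_factor_2log(124.98, 113.70) == pytest.approx(-22.56)

    def test_identity_and_antisymmetry(self):
        assert bayes_factor_2log(5.0, 5.0) == 0.0
        a, b = 12.3, 45.6
        assert bayes_factor_2log(a, b) == -bayes_factor_2log(b, a)

    def test_evidence_bands(self):
        assert "decisive" in kass_raftery_label(16.96)
        assert "negative" in kass_raftery_label(-22.56)
        assert "substantial" in kass_raftery_label(4.0)
        assert "strong" in kass_raftery_label(8.0)
        assert "bare mention" in kass_raftery_label(1.0)


class TestEvaluateRepresentation:
    LMC = LMCConfig(step=2e-3, n_iterations=6_000, burn_in=2_000,
                    thinning=4, seed=0)

    def test_signal_beats_permuted_labels(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(150, 8))
        y = X @ rng.normal(size=8)  # noiseless linear map of the latents
        r_signal = evaluate_representation(X, y, lmc=self.LMC,
                                           architecture="linear")
        y_perm = rng.permutation(y)
        r_null = evaluate_representation(X, y_perm, lmc=self.LMC,
                                         architecture="linear")
        assert r_signal["waic"] < r_null["waic"]
        assert r_signal["wbic"] < r_null["wbic"]

    def test_report_is_seed_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=60)
        cfg = LMCConfig(step=2e-3, n_iterations=2_000, burn_in=500,
                        thinning=5, seed=11)
        a = evaluate_representation(X, y, lmc=cfg, architecture="linear")
        b = evaluate_representation(X, y, lmc=cfg, architecture="linear")
        assert a["waic"] == b["waic"]
        assert a["wbic"] == b["wbic"]

    def test_noisy_encoder_has_higher_wbic(self):
        # corrupting the representation degrades the evidence: majority
        # vote over replicates
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            X = rng.normal(size=(120, 6))
            y = X @ rng.normal(size=6) + 0.2 * rng.normal(size=120)
            X_noisy = X + 3.0 * rng.normal(size=X.shape)
            cfg = LMCConfig(step=2e-3, n_iterations=4_000, burn_in=1_500,
                            thinning=5, seed=rep)
            clean = evaluate_representation(X, y, lmc=cfg,
                                            architecture="linear")
            noisy = evaluate_representation(X_noisy, y, lmc=cfg,
                                            architecture="linear")
            wins += noisy["wbic"] > clean["wbic"]
        assert wins > 5
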