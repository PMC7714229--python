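"""GBLUP model: relationship matrix, REML, Henderson solution, prediction.

The grid oracle used here evaluates the restricted likelihood directly
through log-determinants and linear solves of V = K + lambda * I — a code
path independent of the package's spectral/profiled implementation.
"""

import numpy as np
import pytest

import gpsel as g
from gpsel.gblup import GBLUP, _ProfiledREML


def restricted_loglik_direct(y, K, lam):
    """Independent restricted log-likelihood (profiled sigma2) via slogdet."""
    n = len(y)
    W = K + lam * np.eye(n)
    sign, logdet_W = np.linalg.slogdet(W)
    assert sign > 0
    Wi_y = np.linalg.solve(W, y)
    Wi_1 = np.linalg.solve(W, np.ones(n))
    sxx = np.ones(n) @ Wi_1
    mu = np.ones(n) @ Wi_y / sxx
    r = y - mu
    rss = r @ np.linalg.solve(W, r)
    sigma2 = rss / (n - 1)
    return -0.5 * ((n - 1) * np.log(sigma2) + logdet_W + np.log(sxx))


def grid_oracle_lambda(y, K, n_grid=2000, bracket=(1e-6, 1e6)):
    """Two-stage dense log-grid argmax of the restricted likelihood."""
    grid = np.exp(np.linspace(np.log(bracket[0]), np.log(bracket[1]), n_grid))
    vals = [restricted_loglik_direct(y, K, lam) for lam in grid]
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    fine = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    fvals = [restricted_loglik_direct(y, K, lam) for lam in fine]
    return float(fine[int(np.argmax(fvals))])


def simulate_from_model(K, sigma2_g, sigma2_e, mu, rng):
    n = K.shape[0]
    s, U = np.linalg.eigh(K)
    s = np.maximum(s, 0)
    gvals = U @ (np.sqrt(sigma2_g * s) * rng.standard_normal(n))
    return mu + gvals + rng.normal(0, np.sqrt(sigma2_e), n)


class TestGrm:
    def test_hand_2x2(self):
        M = np.array([[1.0, 1.0], [-1.0, -1.0]])
        np.testing.assert_allclose(g.grm(M), [[1.0, -1.0], [-1.0, 1.0]])

    def test_duplicate_rows(self):
        rng = np.random.default_rng(0)
        M = rng.choice([-1.0, 1.0], size=(3, 40))
        M[2] = M[0]
        K = g.grm(M)
        assert K[0, 0] == K[2, 2] == K[0, 2]

    def test_fully_inbred_unit_diagonal(self):
        rng = np.random.default_rng(1)
        M = rng.choice([-1.0, 1.0], size=(5, 30))
        np.testing.assert_allclose(np.diag(g.grm(M)), 1.0)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            g.grm(np.empty((3, 0)))


class TestHenderson:
    def test_hand_solved_two_individual_system(self):
        mu, ghat = g.solve_henderson(np.array([0.0, 2.0]), np.eye(2), 1.0)
        assert mu == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(ghat, [-0.5, 0.5], atol=1e-12)

    def test_constant_phenotype_no_signal(self):
        rng = np.random.default_rng(2)
        M = rng.choice([-1.0, 1.0], size=(8, 50))
        mu, ghat = g.solve_henderson(np.full(8, 3.7), g.grm(M), 1.0)
        assert mu == pytest.approx(3.7)
        np.testing.assert_allclose(ghat, 0.0, atol=1e-10)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(3)
        M = rng.choice([-1.0, 1.0], size=(10, 50))
        y = rng.normal(size=10)
        mu, ghat = g.solve_henderson(y, g.grm(M), 1e12)
        assert mu == pytest.approx(y.mean(), abs=1e-6)
        np.testing.assert_allclose(ghat, 0.0, atol=1e-8)

    def test_matches_bordered_system_and_closed_form(self):
        """The returned solution satisfies Henderson's printed bordered system."""
        rng = np.random.default_rng(4)
        A = rng.normal(size=(12, 12))
        K = A @ A.T / 12 + 0.5 * np.eye(12)  # invertible PSD
        y = rng.normal(size=12)
        lam = 0.8
        mu, ghat = g.solve_henderson(y, K, lam)
        n = len(y)
        lhs = np.zeros((n + 1, n + 1))
        lhs[0, 0] = n
        lhs[0, 1:] = 1.0
        lhs[1:, 0] = 1.0
        lhs[1:, 1:] = np.eye(n) + lam * np.linalg.inv(K)
        sol = np.linalg.solve(lhs, np.concatenate([[y.sum()], y]))
        assert mu == pytest.approx(sol[0], rel=1e-8)
        np.testing.assert_allclose(ghat, sol[1:], rtol=1e-8, atol=1e-10)
        closed = K @ np.linalg.solve(K + lam * np.eye(n), y - mu)
        np.testing.assert_allclose(ghat, closed, rtol=1e-8)


class TestReml:
    def test_noiseless_limit_hits_lower_boundary(self):
        rng = np.random.default_rng(5)
        M = rng.choice([-1.0, 1.0], size=(30, 100))
        K = g.grm(M)
        y = 1.0 + K @ rng.normal(size=30)  # exact model signal, zero noise
        sigma2_g, sigma2_e, lam = g.reml_fit(y, K)
        assert lam <= 1e-4

    def test_grid_oracle_agreement(self):
        rng = np.random.default_rng(6)
        M = rng.choice([-1.0, 1.0], size=(80, 200))
        K = g.grm(M)
        y = simulate_from_model(K, 2.0, 1.0, 5.0, rng)
        _, _, lam_opt = g.reml_fit(y, K)
        lam_grid = grid_oracle_lambda(y, K)
        assert abs(lam_opt - lam_grid) / lam_grid < 1e-3

    def test_profiled_equals_direct_loglik(self):
        rng = np.random.default_rng(7)
        M = rng.choice([-1.0, 1.0], size=(40, 120))
        K = g.grm(M)
        y = simulate_from_model(K, 1.0, 1.0, 0.0, rng)
        prof = _ProfiledREML(y, K)
        for lam in (0.1, 1.0, 7.3):
            assert prof.loglik(lam) == pytest.approx(
                restricted_loglik_direct(y, K, lam), abs=1e-8
            )

    def test_local_optimality(self):
        rng = np.random.default_rng(8)
        M = rng.choice([-1.0, 1.0], size=(60, 150))
        K = g.grm(M)
        y = simulate_from_model(K, 2.0, 1.0, 0.0, rng)
        _, _, lam = g.reml_fit(y, K)
        prof = _ProfiledREML(y, K)
        assert prof.loglik(lam) >= prof.loglik(0.5 * lam)
        assert prof.loglik(lam) >= prof.loglik(2.0 * lam)

    def test_lambda_recovery_median(self):
        """Median REML lambda over 200 replicates near the true ratio 0.5."""
        rng = np.random.default_rng(9)
        M = rng.choice([-1.0, 1.0], size=(200, 400))
        K = g.grm(M)
        lams = []
        for _ in range(200):
            y = simulate_from_model(K, 2.0, 1.0, 0.0, rng)
            _, _, lam = g.reml_fit(y, K)
            lams.append(lam)
        med = float(np.median(lams))
        assert 0.35 <= med <= 0.70


class TestPredict:
    def test_self_prediction_identity(self, panel, panel_fit):
        gebvs = panel_fit.predict(panel["m"])
        np.testing.assert_allclose(
            gebvs.values, panel_fit.mu_hat + panel_fit.g_hat, atol=1e-10
        )

    def test_f1_midparent_linearity(self, panel_fit):
        rng = np.random.default_rng(10)
        M = panel_fit.M_train
        i, j = 3, 17
        f1 = (M[i] + M[j]) / 2.0
        pred = panel_fit.predict(np.vstack([M[i], M[j], f1]))
        assert pred.values[2] == pytest.approx(
            (pred.values[0] + pred.values[1]) / 2, abs=1e-10
        )

    def test_zero_marker_row_gets_intercept(self, panel_fit):
        pred = panel_fit.predict(np.zeros((1, panel_fit.M_train.shape[1])))
        assert pred.values[0] == pytest.approx(panel_fit.mu_hat, abs=1e-10)

    def test_snp_misalignment_rejected(self, panel, panel_fit):
        m = panel["m"]
        shuffled = m.take_snps(np.arange(m.n_snps)[::-1])
        with pytest.raises(ValueError, match="misalign"):
            panel_fit.predict(shuffled)

    def test_h2_calibration_under_model(self):
        """Mean estimated genomic h2 within +-0.08 of 0.5 when phenotypes are
        simulated from the GBLUP model on a synthetic panel's K."""
        cfg = g.SynthConfig(
            n_accessions=300, n_chromosomes=2, snps_per_chromosome=250,
            het_rate=0.02, missing_rate=0.0, seed=21,
        )
        m, _ = g.make_founders(cfg)
        K = g.grm(m.scores)
        rng = np.random.default_rng(1000)
        h2s = []
        for _ in range(50):
            y = simulate_from_model(K, 1.0, 1.0, 0.0, rng)
            s2g, s2e, _ = g.reml_fit(y, K)
            h2s.append(s2g / (s2g + s2e))
        assert abs(float(np.mean(h2s)) - 0.5) <= 0.08


class TestRrblupEquivalence:
    def test_simulated_dataset(self):
        rng = np.random.default_rng(11)
        M = rng.choice([-1.0, 1.0], size=(50, 300))
        y = rng.normal(size=50)
        assert g.gblup_equals_rrblup_check(M, y) < 1e-6

    def test_single_marker(self):
        rng = np.random.default_rng(12)
        M = rng.choice([-1.0, 1.0], size=(20, 1))
        y = rng.normal(size=20)
        assert g.gblup_equals_rrblup_check(M, y, lam=0.5) < 1e-10

    def test_interpolation_limit(self):
        rng = np.random.default_rng(13)
        M = rng.choice([-1.0, 1.0], size=(15, 200))
        y = rng.normal(size=15)
        assert g.gblup_equals_rrblup_check(M, y, lam=1e-8) < 1e-6


class TestResultsObject:
    def test_summary_mentions_estimates(self, panel_fit):
        text = panel_fit.summary()
        assert "sigma2_g" in text and "lambda" in text

    def test_json_round_trip(self, panel, panel_fit, tmp_path):
        path = tmp_path / "fit.json"
        panel_fit.to_json(path)
        loaded = g.GBLUPResults.from_json(path)
        assert loaded.lam == pytest.approx(panel_fit.lam)
        orig = panel_fit.predict(panel["m"]).values
        re = loaded.predict(panel["m"]).values
        np.testing.assert_allclose(re, orig, atol=1e-6)
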