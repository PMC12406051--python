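"""Trial-amplitude estimators: LS-A, LS-S, uncorrelation matrix, fracridge."""

from unittest.mock import patch

import numpy as np
import pytest

from itemsl.design import TrialWiseDesign
from itemsl.estimators import (
    FRACTION_GRID,
    fracridge_estimate,
    lsa_estimate,
    lss_estimate,
    uncorrelation_matrix,
)
from itemsl.simulation import SimulationConfig, simulate_searchlight

from conftest import make_events
from itemsl.design import build_trialwise_design


def plain_design(Xt, nuisance=0, scan_cov=None):
    t = Xt.shape[1] - nuisance
    return TrialWiseDesign(
        Xt, np.arange(t), np.arange(t, Xt.shape[1]), tr=2.0, scan_cov=scan_cov
    )


class TestLsa:
    def test_identity_design_returns_signal(self):
        sig = np.random.default_rng(0).normal(size=(5, 3))
        est = lsa_estimate(sig, plain_design(np.eye(5)))
        np.testing.assert_allclose(est.gamma_hat, sig, atol=1e-12)

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(1)
        Xt = rng.normal(size=(30, 6))
        gamma = rng.normal(size=(6, 4))
        est = lsa_estimate(Xt @ gamma, plain_design(Xt))
        np.testing.assert_allclose(est.gamma_hat, gamma, atol=1e-9)

    def test_matches_brute_force_gls(self):
        """WLS with non-identity V equals the explicit normal-equations solve."""
        rng = np.random.default_rng(2)
        Xt = rng.normal(size=(20, 5))
        y = rng.normal(size=(20, 3))
        A = rng.normal(size=(20, 20))
        V = A @ A.T + 20 * np.eye(20)
        est = lsa_estimate(y, plain_design(Xt, scan_cov=V))
        Vi = np.linalg.inv(V)
        expected = np.linalg.inv(Xt.T @ Vi @ Xt) @ Xt.T @ Vi @ y
        np.testing.assert_allclose(est.gamma_hat, expected, atol=1e-8)

    def test_residual_orthogonality(self, short_isi_design):
        _, d = short_isi_design
        rng = np.random.default_rng(3)
        y = rng.normal(size=(d.n_scans, 4))
        est = lsa_estimate(y, d)
        # residuals orthogonal to the full design (trial + nuisance columns)
        full_beta = np.linalg.lstsq(d.matrix, y, rcond=None)[0]
        resid = y - d.matrix @ full_beta
        np.testing.assert_allclose(d.matrix.T @ resid, 0, atol=1e-8)
        np.testing.assert_allclose(est.gamma_hat, full_beta[d.trial_columns], atol=1e-8)

    def test_rank_deficient_design_errors(self):
        Xt = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
            lsa_estimate(np.zeros((10, 1)), plain_design(Xt))

    def test_wrong_scan_count_errors(self):
        with pytest.raises(ValueError, match="scans"):
            lsa_estimate(np.zeros((4, 1)), plain_design(np.eye(5)))


class TestLss:
    def test_nonoverlapping_trials_equal_lsa(self):
        ev = make_events([0.0, 40.0, 80.0], 2.0, list("ABA"))
        d = build_trialwise_design(ev, 60, 2.0)
        y = np.random.default_rng(4).normal(size=(60, 3))
        np.testing.assert_allclose(
            lss_estimate(y, d).gamma_hat, lsa_estimate(y, d).gamma_hat, atol=1e-8
        )

    def test_two_trial_hand_oracle(self):
        """4-scan toy solvable by explicit 2x2 normal equations per trial."""
        Xt = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        y = np.array([[1.0], [2.0], [0.5], [0.2]])
        d = plain_design(Xt)
        est = lss_estimate(y, d)
        for i in range(2):
            Xi = np.column_stack([Xt[:, i], Xt[:, 1 - i]])
            beta = np.linalg.inv(Xi.T @ Xi) @ Xi.T @ y
            assert est.gamma_hat[i, 0] == pytest.approx(beta[0, 0], abs=1e-12)

    def test_one_model_fit_per_trial(self):
        ev = make_events(np.arange(100) * 4.0, 2.0)
        d = build_trialwise_design(ev, 220, 2.0)
        y = np.random.default_rng(5).normal(size=(220, 2))
        with patch("numpy.linalg.solve", wraps=np.linalg.solve) as solver:
            lss_estimate(y, d)
            n_fits = sum(
                1 for c in solver.call_args_list if c.args[0].shape[0] <= 4
            )
        assert n_fits == 100

    def test_single_trial_errors(self):
        with pytest.raises(ValueError, match="LS-A"):
            lss_estimate(np.zeros((5, 1)), plain_design(np.eye(5)[:, :1]))


class TestUncorrelationMatrix:
    def test_orthonormal_columns_give_identity(self):
        Q, _ = np.linalg.qr(np.random.default_rng(6).normal(size=(20, 4)))
        np.testing.assert_allclose(
            uncorrelation_matrix(plain_design(Q)), np.eye(4), atol=1e-10
        )

    def test_two_by_two_toy(self):
        Xt = np.array([[1.0, 0.0], [1.0, 1.0]])
        U = uncorrelation_matrix(plain_design(Xt))
        np.testing.assert_allclose(U, [[1.0, -1.0], [-1.0, 2.0]], atol=1e-12)

    def test_short_isi_adjacent_negative_correlation(self):
        cfg = SimulationConfig(isi_range=(0, 4))
        sim = simulate_searchlight(cfg, 0)
        U = uncorrelation_matrix(sim.designs[0])
        adjacent = np.diag(U, 1)
        distant = np.diag(U, 10)
        assert np.mean(adjacent) < 0
        assert np.mean(np.abs(adjacent)) > np.mean(np.abs(distant))

    def test_offdiagonals_shrink_with_isi(self):
        def mean_offdiag(isi):
            sim = simulate_searchlight(
                SimulationConfig(isi_range=isi, trials_per_session=50), 1
            )
            U = uncorrelation_matrix(sim.designs[0])
            return np.mean(np.abs(U - np.diag(np.diag(U))))

        assert mean_offdiag((4, 8)) < mean_offdiag((0, 4))

    def test_includes_nuisance_covariation(self, short_isi_design):
        _, d = short_isi_design
        U = uncorrelation_matrix(d)
        # trial block of the full inverse, not the inverse of the trial block
        full = np.linalg.inv(d.matrix.T @ d.matrix)
        tc = d.trial_columns
        np.testing.assert_allclose(U, full[np.ix_(tc, tc)], atol=1e-12)
        naive = np.linalg.inv(d.trial_matrix.T @ d.trial_matrix)
        assert not np.allclose(U, naive)


class TestFracridge:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.Xt = rng.normal(size=(40, 8))
        self.y = rng.normal(size=(40, 3))
        self.design = plain_design(self.Xt)

    def test_fraction_one_equals_lsa(self):
        est = fracridge_estimate(self.y, self.design, fractions=[1.0])
        lsa = lsa_estimate(self.y, self.design)
        np.testing.assert_allclose(est.gamma_hat, lsa.gamma_hat, atol=1e-6)

    def test_norm_monotone_in_fraction(self):
        norms = []
        for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            est = fracridge_estimate(self.y, self.design, fractions=[f])
            norms.append(np.linalg.norm(est.gamma_hat, axis=0).sum())
        assert np.all(np.diff(norms) > 0)

    def test_fraction_half_matches_alpha_grid_oracle(self):
        """Direct ridge solve at the alpha matching a 0.5 norm ratio."""
        est = fracridge_estimate(self.y, self.design, fractions=[0.5])
        ols = np.linalg.lstsq(self.Xt, self.y, rcond=None)[0]
        for vi in range(self.y.shape[1]):
            target = 0.5 * np.linalg.norm(ols[:, vi])
            alphas = np.geomspace(1e-6, 1e6, 4000)
            best, best_gap = None, np.inf
            for a in alphas:
                b = np.linalg.solve(
                    self.Xt.T @ self.Xt + a * np.eye(8), self.Xt.T @ self.y[:, vi]
                )
                gap = abs(np.linalg.norm(b) - target)
                if gap < best_gap:
                    best, best_gap = b, gap
            np.testing.assert_allclose(est.gamma_hat[:, vi], best, rtol=2e-2, atol=1e-3)

    def test_selection_requires_multiple_sessions(self):
        with pytest.raises(ValueError, match="sessions"):
            fracridge_estimate(self.y, self.design, fractions=FRACTION_GRID,
                               labels=[np.zeros(8, int)])

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            fracridge_estimate(self.y, self.design, fractions=[0.0])

    def test_cross_validated_selection_runs(self):
        cfg = SimulationConfig(trials_per_session=20, n_voxels=5, noise_var=1.0)
        sim = simulate_searchlight(cfg, 2)
        est = fracridge_estimate(sim.signals, sim.designs,
                                 FRACTION_GRID, labels=sim.labels)
        assert est.gamma_hat.shape == (40, 5)
        assert est.method == "FRACRIDGE"
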