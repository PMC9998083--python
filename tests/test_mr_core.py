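"""IVW estimator, delta-method variance and heterogeneity-based outlier removal."""

import numpy as np
import pytest

from triomr import mr_core


def random_spd(rng, k):
    """Random well-conditioned SPD correlation-like matrix."""
    A = rng.normal(size=(k, k))
    S = A @ A.T + k * np.eye(k)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestIVWEffect:
    def test_proportional_vectors(self):
        beta = np.array([0.1, 0.1, 0.1])
        gamma = np.array([0.05, 0.05, 0.05])
        assert mr_core.ivw_effect(beta, gamma) == pytest.approx(0.5, rel=1e-12)

    def test_null_outcome(self):
        assert mr_core.ivw_effect([0.1, 0.2, 0.3], [0, 0, 0]) == 0.0

    def test_identity_ld_closed_form(self, rng):
        beta = rng.normal(size=8)
        gamma = rng.normal(size=8)
        expected = np.sum(beta * gamma) / np.sum(beta**2)
        assert mr_core.ivw_effect(beta, gamma) == pytest.approx(expected, rel=1e-12)

    def test_matches_explicit_inverse_gls_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 11))
            C = random_spd(rng, k)
            beta = rng.normal(size=k)
            gamma = rng.normal(size=k)
            Cinv = np.linalg.inv(C)
            oracle = (beta @ Cinv @ gamma) / (beta @ Cinv @ beta)
            assert mr_core.ivw_effect(beta, gamma, C) == pytest.approx(
                oracle, rel=1e-10
            )

    def test_degenerate_exposure_rejected(self):
        with pytest.raises(mr_core.DegenerateExposureError):
            mr_core.ivw_effect([0.0, 0.0, 0.0], [0.1, 0.1, 0.1])

    def test_singular_ld_rejected(self):
        C = np.ones((3, 3))
        with pytest.raises(mr_core.LDDecompositionError):
            mr_core.ivw_effect([0.1, 0.2, 0.3], [0.1, 0.1, 0.1], C)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0, -2.0])
    def test_scale_equivariance(self, rng, c):
        beta = rng.normal(size=6)
        gamma = rng.normal(size=6)
        C = random_spd(rng, 6)
        a = mr_core.ivw_effect(beta, gamma, C)
        assert mr_core.ivw_effect(beta, c * gamma, C) == pytest.approx(c * a, rel=1e-10)
        assert mr_core.ivw_effect(c * beta, gamma, C) == pytest.approx(a / c, rel=1e-10)


class TestDeltaVariance:
    def test_outcome_noise_only_closed_form(self, rng):
        beta = rng.normal(size=6)
        gamma = 0.3 * beta
        v = 1 / 300_000
        var = mr_core.delta_variance(beta, gamma, None, 0.3, 0.0, v)
        assert var == pytest.approx(v / np.sum(beta**2), rel=1e-12)

    def test_all_zero_variances(self):
        beta = np.array([0.1, 0.2, 0.15])
        var = mr_core.delta_variance(beta, 0.5 * beta, None, 0.5, 0.0, 0.0)
        assert var == 0.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            mr_core.delta_variance([0.1] * 3, [0.05] * 3, None, 0.5, -1e-6, 0.0)

    def test_matches_monte_carlo_spread(self, rng):
        # reference configuration: 6 IVs, h2-scaled beta, GWAS/eQTL noise
        raw = rng.normal(size=6)
        beta = raw * np.sqrt(0.06 / np.sum(raw**2))
        alpha = 0.035
        gamma = alpha * beta
        vb, vg = 1 / 32_000, 1 / 300_000
        var = mr_core.delta_variance(beta, gamma, None, alpha, vb, vg)
        B = beta + rng.normal(0, np.sqrt(vb), (50_000, 6))
        G = gamma + rng.normal(0, np.sqrt(vg), (50_000, 6))
        alpha_draws = np.sum(B * G, axis=1) / np.sum(B * B, axis=1)
        assert np.sqrt(var) == pytest.approx(alpha_draws.std(), rel=0.15)

    def test_positive_when_outcome_noise_positive(self, rng):
        beta = rng.normal(size=5)
        gamma = rng.normal(size=5)
        var = mr_core.delta_variance(
            beta, gamma, None, mr_core.ivw_effect(beta, gamma), 0.0, 1e-5
        )
        assert var > 0


class TestQOutlierFilter:
    def test_perfect_fit_no_removals(self):
        beta = np.array([0.1, 0.12, 0.08, 0.11])
        gamma = 0.4 * beta
        kept, diag = mr_core.q_outlier_filter(beta, gamma, None, 1e-5, 1e-5)
        assert len(kept) == 4
        np.testing.assert_allclose(diag.T, 0.0, atol=1e-20)
        assert diag.removal_order == []

    def test_planted_outlier_removed_first(self, rng):
        # 8 consistent IVs plus one whose deviation is 10x the gamma noise
        beta = np.full(9, 0.1)
        sd_g = np.sqrt(1 / 300_000)
        gamma = 0.3 * beta + rng.normal(0, sd_g, 9)
        gamma[4] += 10 * sd_g
        ids = [f"s{i}" for i in range(9)]
        kept, diag = mr_core.q_outlier_filter(
            beta, gamma, None, 1 / 32_000, sd_g**2, snp_ids=ids,
        )
        assert diag.removal_order[0] == (0, "s4")
        assert "s4" not in diag.snp_ids

    def test_min_ivs_floor_flags_instead_of_removing(self):
        beta = np.array([0.1, 0.1, 0.1])
        gamma = np.array([0.03, 0.03, 0.3])   # third SNP wildly deviant
        kept, diag = mr_core.q_outlier_filter(
            beta, gamma, None, 1e-6, 1e-5, min_ivs=3,
        )
        assert len(kept) == 3
        assert diag.removal_order == []
        assert "outlier_retained_at_min_ivs" in diag.flags

    def test_terminates_and_respects_floor(self, rng):
        for _ in range(20):
            k = 8
            beta = rng.normal(0.1, 0.03, k)
            gamma = 0.2 * beta + rng.normal(0, 0.05, k)  # heavy heterogeneity
            kept, diag = mr_core.q_outlier_filter(
                beta, gamma, None, 1e-5, 1e-5, min_ivs=3,
            )
            assert len(kept) >= 3
            assert len(diag.removal_order) <= k - 3
            iters = [it for it, _ in diag.removal_order]
            assert iters == sorted(iters)


class TestRunUnivariableMR:
    def test_noiseless_chain_recovery(self):
        beta = np.array([0.12, -0.08, 0.1, 0.09, -0.11, 0.1])
        gamma = 0.5 * beta
        fit = mr_core.run_univariable_mr(
            "gene", "pheno", beta, 0.005, gamma, 0.002,
        )
        assert fit.alpha_hat == pytest.approx(0.5, rel=1e-12)
        assert fit.pvalue < 1e-100
        assert fit.n_ivs_final == 6

    def test_zstat_consistent_with_variance(self, rng):
        beta = rng.normal(0.1, 0.02, 6)
        gamma = 0.3 * beta + rng.normal(0, 0.01, 6)
        fit = mr_core.run_univariable_mr("g", "p", beta, 0.005, gamma, 0.01)
        assert fit.z_stat * np.sqrt(fit.var_alpha) == pytest.approx(
            fit.alpha_hat, rel=1e-10
        )

    def test_sign_flip_equivariance(self, rng):
        beta = rng.normal(0.1, 0.02, 6)
        gamma = 0.3 * beta + rng.normal(0, 0.005, 6)
        fit = mr_core.run_univariable_mr("g", "p", beta, 0.005, gamma, 0.01)
        neg = mr_core.run_univariable_mr("g", "p", beta, 0.005, -gamma, 0.01)
        assert neg.alpha_hat == pytest.approx(-fit.alpha_hat, rel=1e-12)
        assert neg.pvalue == pytest.approx(fit.pvalue, rel=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_core.run_univariable_mr("g", "p", [0.1, 0.1], 0.01, [0.05, 0.05], 0.01)

    def test_rmse_shrinks_as_root_n(self, rng):
        # estimator consistency: log-RMSE vs log-N slope near -1/2
        alpha = 0.2
        sizes = [1_000, 10_000, 100_000]
        rmse = []
        for n in sizes:
            errs = []
            for _ in range(500):
                raw = rng.normal(size=6)
                beta = raw * np.sqrt(0.06 / np.sum(raw**2))
                gamma = alpha * beta + rng.normal(0, np.sqrt(1 / n), 6)
                errs.append(np.sum(beta * gamma) / np.sum(beta**2) - alpha)
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        slope = np.polyfit(np.log(sizes), np.log(rmse), 1)[0]
        assert -0.6 < slope < -0.4
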