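"""MVMR direct effects, mediation decomposition and dilution correction."""

import numpy as np
import pandas as pd
import pytest

from triomr import mvmr_mediation as mv
from triomr import mr_core
from triomr.instruments import InstrumentSet, LDMatrix


def _inst(exposure_id, snp_ids, beta):
    beta = np.asarray(beta, dtype=float)
    return InstrumentSet(
        exposure_id=exposure_id, snp_ids=list(snp_ids), beta=beta,
        se_beta=np.full(len(beta), 0.01), ld=LDMatrix.identity(snp_ids),
    )


def _effects(snp_ids, beta, se=0.01):
    return pd.DataFrame(
        {"std_beta": beta, "std_se": se}, index=list(snp_ids),
    )


class TestBuildJointInstruments:
    def _ld(self, ids, r2=None):
        if r2 is None:
            return LDMatrix.identity(ids)
        return LDMatrix(ids, r2)

    def test_disjoint_union(self, rng):
        t_ids = [f"t{i}" for i in range(6)]
        m_ids = [f"m{i}" for i in range(5)]
        all_ids = t_ids + m_ids
        ld = self._ld(all_ids)
        eff_t = _effects(all_ids, rng.normal(size=11))
        eff_m = _effects(all_ids, rng.normal(size=11))
        joint = mv.build_joint_instruments(
            _inst("g", t_ids, rng.normal(size=6)),
            _inst("m", m_ids, rng.normal(size=5)),
            ld, eff_t, eff_m,
        )
        assert joint.B.shape == (11, 2)
        assert joint.snp_ids == all_ids

    def test_shared_snp_deduplicated(self, rng):
        t_ids = ["s1", "s2", "s3"]
        m_ids = ["s3", "s4", "s5"]
        ids = ["s1", "s2", "s3", "s4", "s5"]
        ld = self._ld(ids)
        joint = mv.build_joint_instruments(
            _inst("g", t_ids, [0.1] * 3), _inst("m", m_ids, [0.1] * 3),
            ld, _effects(ids, [0.1] * 5), _effects(ids, [0.1] * 5),
        )
        assert joint.snp_ids == ids

    def test_cross_set_ld_resolved_in_transcripts_favour(self):
        ids = ["t1", "t2", "t3", "m1", "m2", "m3", "m4"]
        r2 = np.eye(7)
        r2[0, 3] = r2[3, 0] = 0.5    # m1 tags t1
        r2[1, 4] = r2[4, 1] = 0.5    # m2 tags t2
        ld = self._ld(ids, r2)
        with pytest.warns(UserWarning):
            joint = mv.build_joint_instruments(
                _inst("g", ["t1", "t2", "t3"], [0.1] * 3),
                _inst("m", ["m1", "m2", "m3", "m4"], [0.1] * 4),
                ld, _effects(ids, [0.1] * 7), _effects(ids, [0.1] * 7),
            )
        assert joint.snp_ids == ["t1", "t2", "t3", "m3", "m4"]
        assert {s for s, _ in joint.dropped} == {"m1", "m2"}

    def test_missing_cross_layer_effect_dropped(self):
        ids = ["t1", "t2", "t3", "m1"]
        ld = self._ld(ids)
        with pytest.warns(UserWarning):
            joint = mv.build_joint_instruments(
                _inst("g", ["t1", "t2", "t3"], [0.1] * 3),
                _inst("m", ["m1"], [0.1]),
                ld,
                _effects(["t1", "t2", "t3"], [0.1] * 3),   # m1 missing here
                _effects(ids, [0.1] * 4),
            )
        assert joint.snp_ids == ["t1", "t2", "t3"]


class TestMVMRDirectEffect:
    def test_block_orthogonal_collapses_to_univariable(self, rng):
        # transcript instruments + orthogonal indicator column: the direct
        # effect must equal the univariable IVW estimate on the shared IVs
        b_t = rng.normal(0.1, 0.02, 6)
        gamma_t = 0.3 * b_t
        B = np.zeros((9, 2))
        B[:6, 0] = b_t
        B[6:, 1] = [0.1, 0.12, 0.09]
        gamma = np.concatenate([gamma_t, np.zeros(3)])
        direct, _ = mv.mvmr_direct_effect(B, gamma)
        uni = mr_core.ivw_effect(b_t, gamma_t)
        assert direct == pytest.approx(uni, abs=1e-8)

    def test_full_mediation_gives_zero_direct_effect(self, rng):
        # gamma = a_tm * a_mp * beta_t on transcript IVs, a_mp * beta_m on
        # metabolite IVs -> the metabolite column explains everything
        a_tm, a_mp = 0.3, 0.2
        b_t = rng.normal(0.1, 0.02, 6)
        b_m = rng.normal(0.09, 0.02, 5)
        B = np.zeros((11, 2))
        B[:6, 0] = b_t
        B[:6, 1] = a_tm * b_t
        B[6:, 1] = b_m
        gamma = np.concatenate([a_tm * a_mp * b_t, a_mp * b_m])
        direct, _ = mv.mvmr_direct_effect(B, gamma)
        assert direct == pytest.approx(0.0, abs=1e-10)

    def test_null_outcome(self, rng):
        B = rng.normal(0.1, 0.03, size=(8, 2))
        direct, var = mv.mvmr_direct_effect(B, np.zeros(8), var_gamma=1e-5)
        assert direct == pytest.approx(0.0, abs=1e-12)
        assert var > 0

    def test_collinear_columns_rejected(self):
        b = np.array([0.1, 0.12, 0.09, 0.11])
        B = np.column_stack([b, 2 * b])
        with pytest.raises(mv.CollinearityError):
            mv.mvmr_direct_effect(B, 0.3 * b)

    def test_variance_matches_monte_carlo(self, rng):
        # sampling calibration of the delta-method variance
        B0 = np.zeros((11, 2))
        B0[:6, 0] = rng.normal(0.1, 0.02, 6)
        B0[:6, 1] = 0.3 * B0[:6, 0]
        B0[6:, 1] = rng.normal(0.09, 0.01, 5)
        gamma0 = B0 @ np.array([0.02, 0.2])
        vb = np.full((11, 2), [1 / 32_000, 1 / 8_000])
        vg = 1 / 300_000
        _, var = mv.mvmr_direct_effect(B0, gamma0, var_B=vb, var_gamma=np.full(11, vg))
        draws = []
        for _ in range(4000):
            B = B0 + rng.normal(0, np.sqrt(vb))
            g = gamma0 + rng.normal(0, np.sqrt(vg), 11)
            draws.append(mv.mvmr_direct_effect(B, g)[0])
        assert np.sqrt(var) == pytest.approx(np.std(draws), rel=0.15)


class TestDecompose:
    @pytest.mark.parametrize(
        "total, direct, indirect, proportion",
        [(0.10, 0.04, 0.06, 0.4), (0.10, 0.10, 0.0, 1.0), (0.05, -0.05, 0.10, -1.0)],
    )
    def test_arithmetic(self, total, direct, indirect, proportion):
        res = mv.decompose(total, direct)
        assert res.indirect_effect == pytest.approx(indirect)
        assert res.proportion_direct == pytest.approx(proportion)
        # conservation is exact, not approximate
        assert res.direct_effect + res.indirect_effect == res.total_effect

    def test_vanishing_total_flags_undefined_proportion(self):
        res = mv.decompose(0.0, 0.01)
        assert not res.proportion_defined
        assert np.isnan(res.proportion_direct)


class TestDilutionCorrectedSlope:
    def test_zero_noise_leaves_slope_unchanged(self, rng):
        t = rng.normal(0, 0.1, 50)
        d = 0.7 * t
        fit = mv.dilution_corrected_slope(d, t, np.zeros(50), n_boot=50, seed=0)
        assert fit.slope_corrected == pytest.approx(fit.slope_raw, rel=1e-12)
        assert fit.slope_raw == pytest.approx(0.7, rel=1e-10)

    def test_half_noise_ratio_doubles_slope(self):
        # construct sum(SE^2) = 0.5 * sum(total^2) exactly
        t = np.array([1.0, 1.0, 1.0, 1.0])
        se = np.full(4, np.sqrt(0.5))
        d = 0.4 * t
        fit = mv.dilution_corrected_slope(d, t, se, n_boot=10, seed=0)
        assert fit.slope_corrected == pytest.approx(2 * fit.slope_raw, rel=1e-12)

    def test_scale_invariance(self, rng):
        t = rng.normal(0, 0.1, 40)
        d = 0.6 * t + rng.normal(0, 0.01, 40)
        se = np.full(40, 0.02)
        a = mv.dilution_corrected_slope(d, t, se, n_boot=10, seed=1)
        b = mv.dilution_corrected_slope(5 * d, 5 * t, 5 * se, n_boot=10, seed=1)
        assert b.slope_corrected == pytest.approx(a.slope_corrected, rel=1e-10)

    def test_correction_amplifies_magnitude(self, rng):
        t = rng.normal(0, 0.1, 60)
        d = 0.5 * t + rng.normal(0, 0.01, 60)
        fit = mv.dilution_corrected_slope(d, t, np.full(60, 0.03), n_boot=10, seed=2)
        assert abs(fit.slope_corrected) >= abs(fit.slope_raw)

    def test_excess_noise_is_an_error(self):
        t = np.array([0.01, 0.01, 0.01])
        with pytest.raises(mv.DilutionUndefinedError):
            mv.dilution_corrected_slope([0.005] * 3, t, [1.0] * 3, n_boot=10)

    def test_parameter_recovery(self, rng):
        # true proportion 0.8; totals observed with known noise
        n = 500
        t_true = rng.normal(0, 0.08, n)
        se = 0.03
        t_obs = t_true + rng.normal(0, se, n)
        d_obs = 0.8 * t_true + rng.normal(0, 0.01, n)
        fit = mv.dilution_corrected_slope(d_obs, t_obs, np.full(n, se),
                                          n_boot=500, seed=3)
        assert fit.slope_corrected == pytest.approx(0.8, abs=0.05)
        assert fit.ci_low < 0.8 < fit.ci_high
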