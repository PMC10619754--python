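import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtarget.estimators import (
    PER_UNIT_DECREASE,
    PER_UNIT_INCREASE,
    cochran_q,
    egger_correlated,
    ivw_correlated,
    leave_one_out,
    report_direction,
    rescale_effect,
    sensitivity_analysis,
    wald_ratio,
)
from mrtarget.harmonization import InstrumentSet
from mrtarget.summary_io import read_ld_matrix, read_summary_stats
from mrtarget.synthetic_data import make_fixture

from conftest import random_instrument_set


def gls_oracle(gamma, Gamma, sigma_y, rho):
    """Step-by-step GLS arithmetic with explicit matrix inversion."""
    omega = np.outer(sigma_y, sigma_y) * rho
    w = np.linalg.inv(omega)
    denom = gamma @ w @ gamma
    theta = (gamma @ w @ Gamma) / denom
    se = math.sqrt(1.0 / denom)
    return theta, se


def _instr(gamma, sigma_x, Gamma, sigma_y, rho=None, outcome_kind="binary"):
    gamma = np.asarray(gamma, dtype=float)
    if rho is None:
        rho = np.eye(len(gamma))
    return InstrumentSet(
        [f"rs{i}" for i in range(len(gamma))],
        gamma, np.asarray(sigma_x, float), np.asarray(Gamma, float),
        np.asarray(sigma_y, float), rho, outcome_kind=outcome_kind,
    )


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.05, 0.005, 0.01, 0.004)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.08)
        assert est.n_snps == 1 and est.method == "wald"

    def test_null_numerator(self):
        est = wald_ratio(1.0, 0.1, 0.0, 0.1)
        assert est.theta == 0.0 and est.se == pytest.approx(0.1)
        assert est.pvalue == pytest.approx(1.0)

    def test_negative_exposure_beta_flips_sign_not_se(self):
        est = wald_ratio(-0.05, 0.005, 0.01, 0.004)
        assert est.theta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.08)

    def test_zero_gamma_is_error(self):
        with pytest.raises(ValueError, match="gamma = 0"):
            wald_ratio(0.0, 0.005, 0.01, 0.004)

    def test_weak_instrument_warns(self, caplog):
        with caplog.at_level("WARNING"):
            wald_ratio(0.001, 0.005, 0.01, 0.004)
        assert any("weak instrument" in r.message for r in caplog.records)

    def test_second_order_se_adds_exposure_uncertainty(self):
        first = wald_ratio(0.05, 0.005, 0.01, 0.004)
        second = wald_ratio(0.05, 0.005, 0.01, 0.004, second_order_se=True)
        expected = math.sqrt(0.004**2 / 0.05**2 + 0.01**2 * 0.005**2 / 0.05**4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se


class TestIVWCorrelated:
    def test_single_variant_reduces_to_wald(self):
        instr = _instr([0.05], [0.005], [0.01], [0.004])
        est = ivw_correlated(instr)
        ref = wald_ratio(0.05, 0.005, 0.01, 0.004, binary=True)
        assert est.theta == ref.theta and est.se == ref.se
        assert est.method == "wald"

    def test_consensus_ratios_recovered_exactly(self):
        gamma = np.array([0.05, 0.04, 0.03])
        instr = _instr(gamma, [0.005] * 3, 0.2 * gamma, [0.01] * 3)
        assert ivw_correlated(instr).theta == pytest.approx(0.2, abs=1e-14)

    def test_matches_worked_gls_example(self):
        gamma = np.array([0.05, 0.04, 0.03])
        Gamma = np.array([0.012, 0.007, 0.005])
        sigma_y = np.array([0.01, 0.01, 0.01])
        rho = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        theta, se = gls_oracle(gamma, Gamma, sigma_y, rho)
        est = ivw_correlated(_instr(gamma, [0.005] * 3, Gamma, sigma_y, rho))
        assert est.theta == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_identity_ld_equals_classical_fixed_effect_meta(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 11))
            instr = random_instrument_set(rng, m=m)
            instr = InstrumentSet(
                instr.variant_ids, instr.gamma, instr.sigma_x, instr.Gamma,
                instr.sigma_y, np.eye(m), outcome_kind="binary",
            )
            ratios = instr.Gamma / instr.gamma
            weights = (instr.gamma / instr.sigma_y) ** 2
            theta_meta = np.sum(weights * ratios) / np.sum(weights)
            se_meta = math.sqrt(1.0 / np.sum(weights))
            est = ivw_correlated(instr)
            assert est.theta == pytest.approx(theta_meta, abs=1e-10)
            assert est.se == pytest.approx(se_meta, abs=1e-10)

    def test_statsmodels_gls_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        instr = random_instrument_set(rng, m=6)
        omega = np.outer(instr.sigma_y, instr.sigma_y) * instr.rho
        fit = sm.GLS(instr.Gamma, instr.gamma, sigma=omega).fit()
        est = ivw_correlated(instr)
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se**2 == pytest.approx(fit.normalized_cov_params[0, 0], abs=1e-12)

    def test_near_singular_ld_is_conditioned_with_warning(self, caplog):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])  # exact duplicates
        instr = _instr([0.05, 0.05], [0.005] * 2, [0.01, 0.01], [0.01, 0.01], rho)
        with caplog.at_level("WARNING"):
            est = ivw_correlated(instr)
        assert any("singular" in r.message for r in caplog.records)
        assert np.isfinite(est.theta) and np.isfinite(est.se)

    def test_ci_is_symmetric_normal(self, rng):
        instr = random_instrument_set(rng, m=5)
        est = ivw_correlated(instr)
        assert est.ci_high - est.theta == pytest.approx(est.theta - est.ci_low,
                                                        abs=1e-9)


class TestCochranQ:
    def test_perfect_homogeneity_gives_zero(self):
        gamma = np.array([0.05, 0.04, 0.03])
        instr = _instr(gamma, [0.005] * 3, 0.2 * gamma, [0.01] * 3)
        q, df, p = cochran_q(instr, ivw_correlated(instr).theta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_study_closed_form(self):
        # two independent instruments with Wald ratios 0.1 and 0.3
        gamma = np.array([0.05, 0.05])
        Gamma = np.array([0.005, 0.015])
        sigma_y = np.array([0.01, 0.01])
        instr = _instr(gamma, [0.005] * 2, Gamma, sigma_y)
        theta = ivw_correlated(instr).theta
        ratios = Gamma / gamma
        w = (gamma / sigma_y) ** 2
        q_classic = float(np.sum(w * (ratios - theta) ** 2))
        q, df, _ = cochran_q(instr, theta)
        assert q == pytest.approx(q_classic, abs=1e-12)
        assert df == 1

    def test_needs_two_instruments(self):
        instr = _instr([0.05], [0.005], [0.01], [0.004])
        with pytest.raises(ValueError):
            cochran_q(instr, 0.2)


class TestEgger:
    def test_exact_proportionality_gives_zero_intercept(self):
        gamma = np.array([0.02, 0.03, 0.05, 0.06])
        instr = _instr(gamma, [0.002] * 4, 0.2 * gamma, [0.01] * 4)
        a0, a0_se, a0_p, slope = egger_correlated(instr)
        assert a0 == pytest.approx(0.0, abs=1e-14)
        assert slope.theta == pytest.approx(0.2, abs=1e-12)

    def test_exact_linear_relation_recovered(self):
        gamma = np.array([0.02, 0.03, 0.04, 0.05, 0.06])
        instr = _instr(gamma, [0.002] * 5, 0.05 + 0.2 * gamma, [0.01] * 5)
        a0, a0_se, a0_p, slope = egger_correlated(instr)
        assert a0 == pytest.approx(0.05, abs=1e-12)
        assert slope.theta == pytest.approx(0.2, abs=1e-12)
        assert slope.method == "egger_slope"

    def test_pleiotropy_toy_fixture_recovered(self, tmp_path):
        paths = make_fixture("pleiotropy_toy", tmp_path)
        exp = read_summary_stats(paths["exposure"])
        out = read_summary_stats(paths["outcome"],
                                 trait_meta={"trait_kind": "binary"})
        ld = read_ld_matrix(paths["ld_matrix"], paths["ld_ids"])
        from mrtarget.harmonization import harmonize

        instr, _ = harmonize(exp, out, ld, exp.variant_ids)
        a0, _, _, slope = egger_correlated(instr)
        assert a0 == pytest.approx(0.05, abs=1e-10)
        assert slope.theta == pytest.approx(0.2, abs=1e-10)

    def test_orientation_applied_internally(self):
        gamma = np.array([0.02, -0.03, 0.04, -0.05])
        Gamma = 0.05 * np.abs(gamma) + 0.01  # pleiotropy in oriented frame
        Gamma = np.where(gamma < 0, -Gamma, Gamma)
        instr = _instr(gamma, [0.002] * 4, Gamma, [0.01] * 4)
        a0, _, _, slope = egger_correlated(instr)
        assert a0 == pytest.approx(0.01, abs=1e-12)
        assert slope.theta == pytest.approx(0.05, abs=1e-12)

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from mrtarget.harmonization import orient_positive

        instr = orient_positive(random_instrument_set(rng, m=7))
        omega = np.outer(instr.sigma_y, instr.sigma_y) * instr.rho
        x = np.column_stack([np.ones(instr.m), instr.gamma])
        fit = sm.GLS(instr.Gamma, x, sigma=omega).fit()
        a0, a0_se, _, slope = egger_correlated(instr)
        assert a0 == pytest.approx(fit.params[0], abs=1e-10)
        assert slope.theta == pytest.approx(fit.params[1], abs=1e-10)
        assert a0_se**2 == pytest.approx(fit.normalized_cov_params[0, 0], abs=1e-12)

    def test_requires_three_instruments(self):
        instr = _instr([0.05, 0.04], [0.005] * 2, [0.01, 0.008], [0.01] * 2)
        with pytest.raises(ValueError, match="three"):
            egger_correlated(instr)

    def test_constant_gamma_is_unidentifiable(self):
        instr = _instr([0.05] * 4, [0.005] * 4, [0.01] * 4, [0.01] * 4)
        with pytest.raises(ValueError, match="constant"):
            egger_correlated(instr)


class TestLeaveOneOut:
    def test_two_instruments_reduce_to_opposite_wald_ratios(self):
        instr = _instr([0.05, 0.04], [0.005] * 2, [0.01, 0.012], [0.01, 0.008])
        loo = leave_one_out(instr)
        assert loo[0][0] == "rs0"
        assert loo[0][1].theta == pytest.approx(0.012 / 0.04)
        assert loo[1][1].theta == pytest.approx(0.01 / 0.05)

    def test_homogeneous_data_stable_under_loo(self):
        gamma = np.array([0.05, 0.04, 0.03, 0.06])
        instr = _instr(gamma, [0.005] * 4, 0.2 * gamma, [0.01] * 4)
        for _, est in leave_one_out(instr):
            assert est.theta == pytest.approx(0.2, abs=1e-12)

    def test_planted_outlier_found_by_largest_shift(self, tmp_path):
        paths = make_fixture("outlier_toy", tmp_path)
        exp = read_summary_stats(paths["exposure"])
        out = read_summary_stats(paths["outcome"],
                                 trait_meta={"trait_kind": "binary"})
        ld = read_ld_matrix(paths["ld_matrix"], paths["ld_ids"])
        from mrtarget.harmonization import harmonize

        instr, _ = harmonize(exp, out, ld, exp.variant_ids)
        full = ivw_correlated(instr).theta
        shifts = {vid: abs(est.theta - full) for vid, est in leave_one_out(instr)}
        assert max(shifts, key=shifts.get) == "rs3"
        # dropping the outlier moves the estimate toward the consensus 0.2
        loo_wo_outlier = dict(leave_one_out(instr))["rs3"].theta
        assert abs(loo_wo_outlier - 0.2) < abs(full - 0.2)


class TestReportingScale:
    def test_decrease_direction_negates_and_exponentiates(self):
        est = wald_ratio(0.05, 0.005, 0.05 * 0.0513, 0.004, binary=True)
        assert est.theta == pytest.approx(0.0513)
        dec = report_direction(est, PER_UNIT_DECREASE)
        assert dec.theta == pytest.approx(-0.0513)
        assert dec.or_scale[0] == pytest.approx(math.exp(-0.0513))
        assert dec.or_scale[0] == pytest.approx(0.95, abs=5e-3)
        assert dec.pvalue == est.pvalue
        assert dec.ci_low == pytest.approx(-est.ci_high)

    def test_null_effect_has_unit_or_either_direction(self):
        est = wald_ratio(1.0, 0.1, 0.0, 0.1, binary=True)
        assert report_direction(est, PER_UNIT_DECREASE).or_scale[0] == pytest.approx(1.0)
        assert est.or_scale[0] == pytest.approx(1.0)

    def test_direction_is_involution(self, rng):
        est = ivw_correlated(random_instrument_set(rng, m=4))
        back = report_direction(
            report_direction(est, PER_UNIT_DECREASE), PER_UNIT_INCREASE
        )
        assert back == est

    def test_rescale_identity_and_inverse(self, rng):
        est = ivw_correlated(random_instrument_set(rng, m=4))
        assert rescale_effect(est, 1.0) == est
        back = rescale_effect(rescale_effect(est, 9.51), 1 / 9.51)
        assert back.theta == pytest.approx(est.theta)
        assert back.se == pytest.approx(est.se)

    def test_rescale_multiplies_theta_se_ci(self, rng):
        est = ivw_correlated(random_instrument_set(rng, m=4))
        scaled = rescale_effect(est, 9.51)
        assert scaled.theta == pytest.approx(est.theta * 9.51)
        assert scaled.se == pytest.approx(est.se * 9.51)
        assert scaled.pvalue == pytest.approx(est.pvalue)
        assert scaled.or_scale[0] == pytest.approx(math.exp(est.theta * 9.51))

    def test_rescale_rejects_nonpositive_units(self, rng):
        est = ivw_correlated(random_instrument_set(rng, m=3))
        with pytest.raises(ValueError):
            rescale_effect(est, 0.0)


class TestSensitivityAnalysis:
    def test_full_battery_for_large_set(self, rng):
        instr = random_instrument_set(rng, m=6)
        rep = sensitivity_analysis(instr)
        assert rep.q_df == 5
        assert len(rep.loo) == 6
        assert rep.egger_slope is not None
        assert rep.pleiotropy_detected in (True, False)

    def test_small_set_omits_unavailable_diagnostics(self, rng):
        instr = random_instrument_set(rng, m=2)
        rep = sensitivity_analysis(instr)
        assert rep.q_df == 1 and len(rep.loo) == 2
        assert rep.egger_slope is None

    def test_single_instrument_gives_empty_report(self, rng):
        instr = random_instrument_set(rng, m=2).subset([0])
        rep = sensitivity_analysis(instr)
        assert rep.q_stat is None and rep.loo == []


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_ivw_matches_explicit_gls_on_random_sets(seed):
    rng = np.random.default_rng(seed)
    instr = random_instrument_set(rng)
    theta, se = gls_oracle(instr.gamma, instr.Gamma, instr.sigma_y, instr.rho)
    est = ivw_correlated(instr)
    assert est.theta == pytest.approx(theta, abs=1e-10)
    assert est.se == pytest.approx(se, abs=1e-10)
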