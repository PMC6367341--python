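"""Stern-Volmer / double-log fitting, inner-filter correction, classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from albind import (
    TitrationSeries, correct_inner_filter, concentration_from_absorbance,
    fit_stern_volmer, fit_double_log, classify_mechanism, classify_affinity,
    QuenchingResult,
)
from albind.synthetic import gen_titration

T_CRIT_4DF = 2.7764  # t(0.975, df=4): 6 nonzero-Q points, 2 fitted params


class TestInnerFilter:
    def test_zero_absorbance_identity(self):
        assert correct_inner_filter(100.0, 0.0, 0.0) == 100.0

    def test_worked_example(self):
        # factor e^((0.10+0.06)/2) = e^0.08
        assert correct_inner_filter(100.0, 0.10, 0.06) == pytest.approx(
            100.0 * np.exp(0.08), abs=1e-9)
        assert correct_inner_filter(100.0, 0.10, 0.06) == pytest.approx(108.329, abs=1e-3)

    def test_monotone_in_absorbance(self):
        low = correct_inner_filter(100.0, 0.10, 0.06)
        high = correct_inner_filter(100.0, 0.20, 0.06)
        assert high > low

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            correct_inner_filter(100.0, -0.1, 0.0)

    @given(c=st.floats(0.1, 100), f=st.floats(1, 1e6),
           a1=st.floats(0, 2), a2=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_commutes_with_intensity_scaling(self, c, f, a1, a2):
        assert correct_inner_filter(c * f, a1, a2) == pytest.approx(
            c * correct_inner_filter(f, a1, a2), rel=1e-12)


class TestBeerLambert:
    def test_protein_stock_example(self):
        # 0.737 absorbance units / 36 850 L/mol/cm -> the 20 uM stock
        assert concentration_from_absorbance(0.7370, 36850, 1.0) == pytest.approx(
            2.0e-5, rel=1e-12)

    def test_zero_and_linearity(self):
        assert concentration_from_absorbance(0.0, 36850) == 0.0
        one = concentration_from_absorbance(0.3, 36850)
        assert concentration_from_absorbance(0.6, 36850) == pytest.approx(2 * one)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            concentration_from_absorbance(0.5, -1.0)


class TestTitrationSeries:
    def test_requires_single_reference_point(self):
        with pytest.raises(ValueError, match="reference intensity"):
            TitrationSeries(298.0, Q=[1e-6, 2e-6, 3e-6], F=[90, 80, 70])

    def test_requires_increasing_q(self):
        with pytest.raises(ValueError):
            TitrationSeries(298.0, Q=[0, 2e-6, 2e-6], F=[100, 80, 70])

    def test_f0_is_reference_intensity(self):
        s = gen_titration(K=1e5, F0=1234.5)
        assert s.F0 == pytest.approx(1234.5)


class TestSternVolmer:
    def test_constant_intensity_gives_zero_ksv(self):
        s = TitrationSeries(298.0, Q=np.arange(5) * 1e-6,
                            F=np.full(5, 100.0))
        res = fit_stern_volmer(s)
        assert res.K_SV == pytest.approx(0.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0)

    def test_noiseless_recovery_is_exact(self):
        s = gen_titration(K=1.26e5)
        res = fit_stern_volmer(s)
        assert res.K_SV == pytest.approx(1.26e5, rel=1e-10)
        assert res.intercept == pytest.approx(1.0, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_unit_invariance(self):
        # only the ratio F0/F enters, so intensity units cancel
        a = gen_titration(K=1.26e5, F0=1000.0)
        b = TitrationSeries(a.temperature, a.Q, a.F * 37.2, a.A_ex, a.A_em)
        assert fit_stern_volmer(a).K_SV == pytest.approx(
            fit_stern_volmer(b).K_SV, rel=1e-12)

    def test_monte_carlo_mean_recovery(self):
        # 1% multiplicative noise, 200 seeds: mean K_SV within 2% of truth
        est = [fit_stern_volmer(gen_titration(K=1.26e5, noise_cv=0.01,
                                              seed=s)).K_SV
               for s in range(200)]
        assert abs(np.mean(est) - 1.26e5) / 1.26e5 < 0.02

    def test_too_few_points(self):
        s = TitrationSeries(298.0, Q=[0, 1e-6, 2e-6], F=[100, 90, 80])
        with pytest.raises(ValueError, match="at least 3"):
            fit_stern_volmer(s)


class TestDoubleLog:
    def test_noiseless_recovery_matches_truth(self):
        # K_a = 1.14e5, n = 1: intercept = log10(K_a) = 5.0569
        res = fit_double_log(gen_titration(K=1.14e5, n=1.0))
        assert np.log10(res.K_a) == pytest.approx(5.0569, abs=1e-3)
        assert res.K_a == pytest.approx(1.14e5, rel=1e-10)
        assert res.n == pytest.approx(1.0, rel=1e-10)

    def test_constructed_hill_coefficient(self):
        res = fit_double_log(gen_titration(K=5e4, n=1.3))
        assert res.n == pytest.approx(1.3, rel=1e-9)

    def test_points_above_f0_dropped_with_warning(self):
        s = gen_titration(K=1.14e5)
        F = s.F.copy()
        F[1] = s.F0 * 1.01  # unquenched outlier at lowest [Q]
        s2 = TitrationSeries(s.temperature, s.Q, F, s.A_ex, s.A_em)
        with pytest.warns(UserWarning, match="F >= F0"):
            res = fit_double_log(s2)
        assert res.K_a == pytest.approx(1.14e5, rel=1e-6)

    def test_monte_carlo_bias_below_3_percent(self):
        # K_a comes from the regression intercept, i.e. it is a log-scale
        # estimate; recovery is therefore assessed on the geometric mean
        # (the arithmetic mean is Jensen-inflated by the intercept scatter)
        est = [fit_double_log(gen_titration(K=1.14e5, noise_cv=0.01,
                                            seed=s)).K_a
               for s in range(200)]
        geo_mean = 10.0 ** np.mean(np.log10(est))
        assert abs(geo_mean - 1.14e5) / 1.14e5 < 0.03


def test_sv_and_double_log_agree_for_single_site_static():
    # both estimate the association constant when n = 1 and quenching is static
    s = gen_titration(K=1.14e5, n=1.0)
    ksv = fit_stern_volmer(s).K_SV
    ka = fit_double_log(s).K_a
    assert abs(ksv - ka) / ka < 0.01


def test_ci_coverage_of_linear_fits():
    # 95% t-intervals should cover truth in >= 90% of 200 noisy datasets
    cover_sv = cover_ka = 0
    for s in range(200):
        series = gen_titration(K=1.14e5, noise_cv=0.01, seed=s)
        sv = fit_stern_volmer(series)
        if abs(sv.K_SV - 1.14e5) <= T_CRIT_4DF * sv.K_SV_stderr:
            cover_sv += 1
        dl = fit_double_log(series)
        half = T_CRIT_4DF * dl.K_a_stderr / (dl.K_a * np.log(10.0))
        if abs(np.log10(dl.K_a) - np.log10(1.14e5)) <= half:
            cover_ka += 1
    assert cover_sv >= 180
    assert cover_ka >= 180


def _qres(ksv, T):
    return QuenchingResult(K_SV=ksv, K_SV_stderr=0.0, intercept=1.0,
                           r_squared=1.0, temperature=T)


class TestMechanism:
    def test_decreasing_ksv_with_stable_lifetime_is_static(self):
        results = [_qres(1.26e5, 298), _qres(1.11e5, 304), _qres(1.00e5, 310)]
        assert classify_mechanism(results, lifetime_change=0.017) == "static"

    def test_increasing_ksv_with_shortened_lifetime_is_dynamic(self):
        results = [_qres(1.0e5, 298), _qres(1.2e5, 304), _qres(1.4e5, 310)]
        assert classify_mechanism(results, lifetime_change=-0.30) == "dynamic"

    def test_single_temperature_is_inconclusive(self):
        assert classify_mechanism([_qres(1.26e5, 298)]) == "inconclusive"

    def test_static_without_lifetime_evidence(self):
        results = [_qres(1.26e5, 298), _qres(1.00e5, 310)]
        assert classify_mechanism(results, lifetime_change=None) == "static"


@pytest.mark.parametrize("ka,label", [
    (1.14e5, "moderate"), (1e2, "weak"), (1e7, "strong"),
    (1e3, "moderate"), (1e6, "moderate"),
])
def test_affinity_classes(ka, label):
    assert classify_affinity(ka) == label
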