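"""Closed-form model curves, the mutation recursion and their bridges."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from weibinc import (
    GammaParams,
    PowerLawParams,
    TlirParams,
    WeibullParams,
    generations,
    lambda_from_tlir,
    mutation_hit_prob_closed_form,
    mutation_pmf_recursion,
    power_law_incidence,
    scaled_gamma_incidence,
    scaled_weibull_incidence,
    scaled_weibull_saturating,
    tissue_risk,
    tlir,
    weibull_cdf,
)

AGES = np.linspace(0.5, 84.5, 85)


class TestWeibullCdf:
    def test_origin_and_scale_point(self):
        assert weibull_cdf(0.0, 50.0, 4.0) == 0.0
        for lam, k in [(10.0, 1.0), (90.0, 6.0), (2.0, 0.5)]:
            assert weibull_cdf(lam, lam, k) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_direct_evaluation(self):
        # independent arithmetic for 1 - exp(-(85/200)^5)
        expected = 1.0 - math.e ** (-((85.0 / 200.0) ** 5))
        assert weibull_cdf(85.0, 200.0, 5.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("lam,k", [(0.0, 2.0), (-1.0, 2.0), (10.0, 0.0), (10.0, -3.0)])
    def test_domain_errors(self, lam, k):
        with pytest.raises(ValueError):
            weibull_cdf(1.0, lam, k)


class TestScaledWeibull:
    def test_exponential_special_case(self):
        p = WeibullParams(P=2.0, lambda_=10.0, k=1.0)
        assert scaled_weibull_incidence(10.0, p) == pytest.approx(2 * (1 - math.exp(-1)), rel=1e-12)
        assert scaled_weibull_incidence(0.0, p) == 0.0

    def test_matches_brute_force(self):
        p = WeibullParams(P=0.05, lambda_=90.0, k=6.0)
        brute = 0.05 * (1.0 - np.exp(-((85.0 / 90.0) ** 6.0)))
        assert scaled_weibull_incidence(85.0, p) == pytest.approx(brute, rel=1e-12)

    def test_saturating_identity_at_P1_and_bound(self):
        p1 = WeibullParams(P=1.0, lambda_=80.0, k=3.0)
        assert scaled_weibull_saturating(AGES, p1) == pytest.approx(
            weibull_cdf(AGES, 80.0, 3.0), rel=1e-12)
        pbig = WeibullParams(P=1e4, lambda_=1e4, k=3.0)
        lin = scaled_weibull_incidence(AGES, pbig)
        sat = scaled_weibull_saturating(AGES, pbig)
        assert np.all(sat <= lin + 1e-15)
        assert np.all(sat >= 0) and np.all(sat <= 1)

    def test_poisson_approximation_regime(self):
        # linear and saturating forms agree to 1% while P*W <= 0.02
        p = WeibullParams(P=1e4, lambda_=1e4, k=3.0)
        ages = np.linspace(1.0, 50.0, 200)
        lin = scaled_weibull_incidence(ages, p)
        sat = scaled_weibull_saturating(ages, p)
        small = lin <= 0.02
        assert small.any()
        rel = np.abs(sat[small] - lin[small]) / lin[small]
        assert rel.max() < 0.01


class TestMutationRecursion:
    def test_initial_condition(self):
        pmf = mutation_pmf_recursion(3, 0, 0.1)
        assert pmf.probs == pytest.approx([1, 0, 0, 0], abs=0)

    def test_single_transition_hand_iterated(self):
        pmf = mutation_pmf_recursion(2, 1, 0.1)
        assert pmf.probs == pytest.approx([0.81, 0.18, 0.01], abs=1e-15)

    def test_full_hit_closed_form(self):
        pmf = mutation_pmf_recursion(3, 10, 0.01)
        assert pmf.probs[3] == pytest.approx((1 - 0.99 ** 10) ** 3, rel=1e-12)

    @pytest.mark.parametrize("k,g,r", [(1, 1, 0.25), (5, 100, 1e-3), (8, 200, 1e-6), (2, 50, 0.0)])
    def test_closed_form_matches_recursion(self, k, g, r):
        pmf = mutation_pmf_recursion(k, g, r)
        assert mutation_hit_prob_closed_form(k, g, r) == pytest.approx(
            pmf.probs[k], abs=1e-10, rel=1e-10) or (r == 0.0 and pmf.probs[k] == 0.0)

    @given(k=st.integers(0, 8), g=st.integers(0, 200),
           r=st.sampled_from([0.0, 1e-6, 1e-3, 0.1]))
    @settings(max_examples=60, deadline=None)
    def test_pmf_conserves_mass_and_matches_binomial(self, k, g, r):
        """The marginal after g divisions is Binomial(k, 1-(1-r)^g)."""
        pmf = mutation_pmf_recursion(k, g, r)
        assert abs(pmf.probs.sum() - 1.0) <= 1e-12
        q = -math.expm1(g * math.log1p(-r))
        expected = stats.binom.pmf(np.arange(k + 1), k, q)
        np.testing.assert_allclose(pmf.probs, expected, atol=1e-10)

    @pytest.mark.parametrize("k,g,r", [(-1, 1, 0.1), (1, -1, 0.1), (1, 1, 1.0), (1, 1, -0.1)])
    def test_domain_errors(self, k, g, r):
        with pytest.raises(ValueError):
            mutation_pmf_recursion(k, g, r)

    def test_closed_form_trivial_values(self):
        assert mutation_hit_prob_closed_form(4.0, 7.0, 0.0) == 0.0
        assert mutation_hit_prob_closed_form(1.0, 1.0, 0.25) == pytest.approx(0.25, abs=1e-15)


class TestGenerations:
    @pytest.mark.parametrize("S,d,expected", [
        (1.35e8, 12.0, 1047.01),   # acute myeloid leukemia
        (2.00e8, 73.0, 6232.58),   # colorectal adenocarcinoma
        (3.80e9, 2.48, 242.62),    # melanoma
        (1.22e9, 0.07, 36.13),     # lung adenocarcinoma
        (8.64e5, 17.4, 1498.72),   # esophageal squamous cell carcinoma
        (1.85e7, 21.5, 1851.64),   # head and neck squamous cell carcinoma
    ])
    def test_lifetime_generation_counts(self, S, d, expected):
        assert generations(S, d, 85.0) == pytest.approx(expected, abs=0.005)

    def test_single_cell_no_divisions(self):
        assert generations(1.0, 0.0, 85.0) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            generations(0.5, 1.0, 10.0)


class TestTlir:
    def test_zero_mutation_rate(self):
        p = TlirParams(S=1e8, r=0.0, d=10.0, k=3.0)
        assert tlir(85.0, p) == 0.0

    def test_single_cell_single_hit(self):
        # S=1, d=1, k=1, r=0.5 at age 1: one division, hit probability 1/2
        p = TlirParams(S=1.0, r=0.5, d=1.0, k=1.0)
        assert tlir(1.0, p) == pytest.approx(0.5, rel=1e-12)

    def test_matches_recursion_composition(self):
        # integer k, generations rounded to the nearest integer
        S, d, r, k = 1.35e8, 12.0, 1e-6, 5
        n = round(generations(S, d, 85.0))
        p_cell = mutation_pmf_recursion(k, n, r).probs[k]
        expected = tissue_risk(p_cell, S)
        # evaluate the closed form at the age whose generation count is exactly n
        a = (n - math.log2(S)) / d
        assert tlir(a, TlirParams(S=S, r=r, d=d, k=float(k))) == pytest.approx(
            expected, rel=1e-10)

    def test_no_underflow_for_tiny_inner_probability(self):
        # inner per-cell probability ~1e-90, far below 1/S
        p = TlirParams(S=1e10, r=1e-10, d=1.0, k=6.0)
        val = tlir(85.0, p)
        assert val > 0
        assert val == pytest.approx(1e10 * mutation_hit_prob_closed_form(
            6.0, generations(1e10, 1.0, 85.0), 1e-10), rel=1e-6)

    def test_monotone_and_bounded(self):
        p = TlirParams(S=1e8, r=5e-7, d=20.0, k=5.0)
        vals = tlir(AGES, p)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0) & (vals <= 1))


class TestLambdaBridge:
    def test_algebraic_rearrangement(self):
        p = TlirParams(S=1e8, r=1e-6, d=10.0, k=3.0)
        lam = lambda_from_tlir(p, P=1e3)
        assert lam == pytest.approx(1e10 ** (1 / 3), rel=1e-10)
        # substitute back: S (r d)^k lambda^k / P = 1
        identity = p.S * (p.r * p.d) ** p.k * lam ** p.k / 1e3
        assert identity == pytest.approx(1.0, rel=1e-10)

    def test_P_equals_S_special_case(self):
        for k in (1.0, 3.0, 7.5):
            p = TlirParams(S=1e8, r=2e-6, d=5.0, k=k)
            assert lambda_from_tlir(p, P=1e8) == pytest.approx(1e5, rel=1e-10)

    def test_zero_rate_error(self):
        with pytest.raises(ValueError):
            lambda_from_tlir(TlirParams(S=1e8, r=0.0, d=5.0, k=2.0), P=1.0)


class TestWeibullApproximationRegime:
    @pytest.mark.parametrize("S,d,r,k", [
        (1e5, 20.0, 1e-6, 3.0),
        (1e6, 25.0, 1e-6, 5.0),
        (1e4, 15.0, 1e-5, 2.0),
        (1e6, 30.0, 5e-6, 4.0),
        (1e7, 60.0, 1e-7, 6.0),
    ])
    def test_tlir_close_to_saturating_weibull(self, S, d, r, k):
        """With P=S and lambda=1/(rd), the tissue-risk curve and the
        saturating scaled Weibull agree within 5% of the lifetime risk
        when divisions dominate the developmental offset."""
        ages = np.linspace(20.0, 85.0, 131)
        assert d * ages.min() >= 20 * math.log2(S)  # regime condition
        tp = TlirParams(S=S, r=r, d=d, k=k)
        wp = WeibullParams(P=S, lambda_=1.0 / (r * d), k=k)
        dev = np.max(np.abs(tlir(ages, tp) - scaled_weibull_saturating(ages, wp)))
        assert dev / tlir(85.0, tp) <= 0.05


class TestGammaAndPowerLaw:
    def test_gamma_zero_and_exponential_case(self):
        p = GammaParams(P=0.7, shape=1.0, scale=15.0)
        assert scaled_gamma_incidence(0.0, p) == 0.0
        ages = np.array([5.0, 30.0, 80.0])
        np.testing.assert_allclose(scaled_gamma_incidence(ages, p),
                                   0.7 * (1 - np.exp(-ages / 15.0)), rtol=1e-12)

    def test_gamma_against_series_oracle(self):
        # independent evaluation of the regularized lower incomplete Gamma
        # at integer shape via the Poisson-sum identity
        shape, scale, a = 6, 12.0, 60.0
        x = a / scale
        poisson_tail = 1.0 - sum(math.exp(-x) * x ** i / math.factorial(i)
                                 for i in range(shape))
        p = GammaParams(P=0.1, shape=float(shape), scale=scale)
        assert scaled_gamma_incidence(a, p) == pytest.approx(0.1 * poisson_tail, rel=1e-12)

    def test_gamma_monotone(self):
        p = GammaParams(P=0.1, shape=6.0, scale=12.0)
        assert np.all(np.diff(scaled_gamma_incidence(AGES, p)) >= 0)

    def test_power_law_values_and_loglog_slope(self):
        p = PowerLawParams(c=1e-10, m=5.0)
        assert power_law_incidence(10.0, p) == pytest.approx(1e-5, rel=1e-12)
        ages = np.linspace(1.0, 85.0, 50)
        slope = np.polyfit(np.log(ages), np.log(power_law_incidence(ages, p)), 1)[0]
        assert slope == pytest.approx(5.0, abs=1e-10)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            GammaParams(P=0.1, shape=-1.0, scale=2.0)
        with pytest.raises(ValueError):
            PowerLawParams(c=1.0, m=0.0)


@given(a=st.floats(0.0, 85.0), b=st.floats(0.0, 85.0))
@settings(max_examples=40, deadline=None)
def test_all_families_monotone_in_age(a, b):
    lo, hi = sorted([a, b])
    params = [
        (scaled_weibull_incidence, WeibullParams(P=0.05, lambda_=90.0, k=6.0)),
        (scaled_weibull_saturating, WeibullParams(P=30.0, lambda_=500.0, k=4.0)),
        (scaled_gamma_incidence, GammaParams(P=0.1, shape=5.0, scale=14.0)),
        (power_law_incidence, PowerLawParams(c=1e-9, m=4.0)),
        (tlir, TlirParams(S=1e7, r=1e-6, d=20.0, k=4.0)),
    ]
    for fn, p in params:
        assert fn(hi, p) >= fn(lo, p) - 1e-15


def test_param_bundles_json_round_trip():
    for p in (WeibullParams(P=0.05, lambda_=90.0, k=6.0),
              GammaParams(P=0.1, shape=6.0, scale=12.0),
              PowerLawParams(c=1e-9, m=4.5),
              TlirParams(S=1e8, r=1e-6, d=12.0, k=4.8)):
        assert type(p).from_json(p.to_json()) == p
    assert set(WeibullParams(P=1, lambda_=2, k=3).to_dict()) == {"P", "lambda", "k"}
    assert set(TlirParams(S=1e8, r=1e-6, d=1, k=2).to_dict()) == {"S", "r", "d", "k"}
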