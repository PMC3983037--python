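import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gremlpower import (
    BivariateDesign,
    CaseControlDesign,
    UnivariateDesign,
    make_liability_model,
    ratio_same_vs_diff,
    se_h2_cc_liab,
    var_h2_cc_obs,
    var_h2_qt,
    var_rg_cc_cc,
    var_rg_diff_samples,
    var_rg_qt_cc,
    var_rg_same_sample,
)


class TestUnivariate:
    @pytest.mark.parametrize("n, expected", [(3925, 0.081), (11586, 0.027)])
    def test_reported_study_sizes(self, n, expected):
        assert round(math.sqrt(var_h2_qt(UnivariateDesign(n=n))), 3) == expected

    def test_se_independent_of_heritability(self):
        assert var_h2_qt(UnivariateDesign(n=5000, h2=0.1)) == var_h2_qt(
            UnivariateDesign(n=5000, h2=0.9)
        )

    def test_doubling_n_halves_se(self):
        se1 = math.sqrt(var_h2_qt(UnivariateDesign(n=4000)))
        se2 = math.sqrt(var_h2_qt(UnivariateDesign(n=8000)))
        assert se1 == pytest.approx(2 * se2, rel=1e-12)

    @given(n=st.integers(2, 10**6), var_pi=st.floats(1e-7, 1e-2))
    def test_positive_and_inverse_in_var_pi(self, n, var_pi):
        v = var_h2_qt(UnivariateDesign(n=n, var_pi=var_pi))
        assert v > 0
        assert v * var_pi == pytest.approx(2 / n**2, rel=1e-12)

    def test_invalid_design_parameters(self):
        with pytest.raises(ValueError):
            UnivariateDesign(n=1)
        with pytest.raises(ValueError):
            UnivariateDesign(n=100, h2=1.5)
        with pytest.raises(ValueError):
            UnivariateDesign(n=100, var_pi=0.0)


class TestCaseControlObserved:
    @pytest.mark.parametrize(
        "n_cases, n_controls, expected",
        [(1604, 1953, 0.089), (9087, 12171, 0.015)],
    )
    def test_published_rows(self, n_cases, n_controls, expected):
        d = CaseControlDesign(n_cases=n_cases, n_controls=n_controls, prevalence=0.01)
        assert round(math.sqrt(var_h2_cc_obs(d)), 3) == expected

    def test_depends_on_total_only(self):
        a = CaseControlDesign(n_cases=1000, n_controls=3000, prevalence=0.1)
        b = CaseControlDesign(n_cases=3000, n_controls=1000, prevalence=0.1)
        assert var_h2_cc_obs(a) == var_h2_cc_obs(b)


class TestCaseControlLiability:
    def test_symmetric_design_scales_observed_se_by_pi_over_two(self):
        d = CaseControlDesign(
            n_cases=1779, n_controls=1778, prevalence=0.5, case_fraction=0.5
        )
        se_obs = math.sqrt(var_h2_cc_obs(d))
        assert se_h2_cc_liab(d) == pytest.approx(se_obs * math.pi / 2, rel=1e-10)

    def test_liability_over_observed_ratio_is_c_exactly(self):
        d = CaseControlDesign(n_cases=5000, n_controls=16258, prevalence=0.01)
        ratio = se_h2_cc_liab(d) / math.sqrt(var_h2_cc_obs(d))
        assert ratio == pytest.approx(d.liability.c, rel=1e-12)

    def test_rare_disease_value_from_frozen_oracle_factor(self):
        d = CaseControlDesign(
            n_cases=10629, n_controls=10629, prevalence=0.01, case_fraction=0.5
        )
        se_obs = math.sqrt(var_h2_cc_obs(d))
        assert se_h2_cc_liab(d) == pytest.approx(se_obs * 0.551907298063, rel=1e-9)

    def test_case_fraction_defaults_to_counts(self):
        d = CaseControlDesign(n_cases=1000, n_controls=3000, prevalence=0.05)
        assert d.v == pytest.approx(0.25)
        override = CaseControlDesign(
            n_cases=1000, n_controls=3000, prevalence=0.05, case_fraction=0.5
        )
        assert override.v == 0.5


class TestSameSample:
    def test_independent_traits_closed_form(self):
        d = BivariateDesign(
            mode="same_sample", n1=4000, h2_1=0.5, h2_2=0.5, rg=0.0, rp=0.0
        )
        v = var_rg_same_sample(d)
        assert v == pytest.approx(1 / (4000**2 * 2e-5 * 0.25), rel=1e-12)
        assert math.sqrt(v) == pytest.approx(0.1118, abs=5e-5)

    def test_published_same_sample_prediction_within_5pct(self):
        # the published Table-1 value 0.114 used the empirical relatedness
        # variance of real genotype data; 2e-5 theory must agree within 5%
        d = BivariateDesign(
            mode="same_sample", n1=4000, h2_1=0.5, h2_2=0.5, rg=0.0, rp=0.0
        )
        assert math.sqrt(var_rg_same_sample(d)) == pytest.approx(0.114, rel=0.05)

    def test_intelligence_example_se(self):
        # childhood vs old-age intelligence: N=1729, rG~0.62, reported h2 of
        # 0.48 and 0.28, phenotypic stability ~0.63; predicted SE printed 0.22
        d = BivariateDesign(
            mode="same_sample", n1=1729, h2_1=0.48, h2_2=0.28, rg=0.62, rp=0.63,
        )
        assert math.sqrt(var_rg_same_sample(d)) == pytest.approx(0.22, abs=0.01)

    def test_perfect_correlation_limit_vanishes_continuously(self):
        exact = BivariateDesign(mode="same_sample", n1=3000, h2_1=0.4, h2_2=0.4,
                                rg=1.0, rp=1.0)
        assert var_rg_same_sample(exact) == 0.0
        near = BivariateDesign(mode="same_sample", n1=3000, h2_1=0.4, h2_2=0.4,
                               rg=0.999, rp=0.999)
        assert 0 < var_rg_same_sample(near) < 1e-5

    def test_missing_rp_is_a_configuration_error(self):
        d = BivariateDesign(mode="same_sample", n1=3000, h2_1=0.4, h2_2=0.4, rg=0.2)
        with pytest.raises(ValueError, match="rp"):
            var_rg_same_sample(d)

    def test_zero_heritability_rejected_and_tiny_warns(self):
        with pytest.raises(ValueError, match="h2"):
            var_rg_same_sample(
                BivariateDesign(mode="same_sample", n1=3000, h2_1=0.0, h2_2=0.4,
                                rg=0.2, rp=0.1)
            )
        with pytest.warns(UserWarning):
            var_rg_same_sample(
                BivariateDesign(mode="same_sample", n1=3000, h2_1=5e-4, h2_2=0.4,
                                rg=0.2, rp=0.1)
            )


class TestDifferentSamples:
    @pytest.mark.parametrize(
        "n1, n2, h1, h2, rg, expected",
        [
            (17012, 11922, 0.40, 0.39, 0.68, 0.049),
            (19436, 16821, 0.38, 0.16, 0.43, 0.057),
        ],
    )
    def test_published_psychiatric_rows(self, n1, n2, h1, h2, rg, expected):
        d = BivariateDesign(
            mode="different_samples", n1=n1, n2=n2, h2_1=h1, h2_2=h2, rg=rg
        )
        assert round(math.sqrt(var_rg_diff_samples(d)), 3) == expected

    def test_independent_traits_limit_and_set_symmetry(self):
        d = BivariateDesign(mode="different_samples", n1=2000, n2=5000,
                            h2_1=0.3, h2_2=0.6, rg=0.0)
        assert var_rg_diff_samples(d) == pytest.approx(
            1 / (0.3 * 0.6 * 2000 * 5000 * 2e-5), rel=1e-12
        )
        swapped = BivariateDesign(mode="different_samples", n1=5000, n2=2000,
                                  h2_1=0.6, h2_2=0.3, rg=0.0)
        assert var_rg_diff_samples(d) == pytest.approx(var_rg_diff_samples(swapped))

    @given(rg=st.floats(-1.0, 1.0))
    def test_never_below_independent_trait_limit(self, rg):
        base = BivariateDesign(mode="different_samples", n1=3000, n2=4000,
                               h2_1=0.4, h2_2=0.3, rg=0.0)
        d = BivariateDesign(mode="different_samples", n1=3000, n2=4000,
                            h2_1=0.4, h2_2=0.3, rg=rg)
        assert var_rg_diff_samples(d) >= var_rg_diff_samples(base)

    def test_rp_forbidden(self):
        with pytest.raises(ValueError, match="rp"):
            BivariateDesign(mode="different_samples", n1=2000, n2=2000,
                            h2_1=0.4, h2_2=0.4, rg=0.2, rp=0.1)

    def test_monotone_decreasing_in_each_size_and_heritability(self):
        def v(**kw):
            base = dict(mode="different_samples", n1=3000, n2=4000,
                        h2_1=0.4, h2_2=0.3, rg=0.5)
            base.update(kw)
            return var_rg_diff_samples(BivariateDesign(**base))

        assert v(n1=6000) < v()
        assert v(n2=8000) < v()
        assert v(h2_1=0.8) < v()
        assert v(h2_2=0.6) < v()


class TestCaseControlBivariate:
    def test_published_scz_adhd_row(self):
        v = var_rg_cc_cc(19128, 14044, 0.08, h2_obs_1=0.42, h2_obs_2=0.22)
        assert round(math.sqrt(v), 3) == 0.045

    def test_liability_inputs_equal_preconverted_observed(self):
        m1 = make_liability_model(0.01, 0.5)
        m2 = make_liability_model(0.1, 0.4)
        h2_liab_1, h2_liab_2 = 0.23, 0.30
        via_liab = var_rg_cc_cc(
            10000, 12000, 0.4,
            h2_liab_1=h2_liab_1, prevalence_1=0.01, case_fraction_1=0.5,
            h2_liab_2=h2_liab_2, prevalence_2=0.1, case_fraction_2=0.4,
        )
        via_obs = var_rg_cc_cc(
            10000, 12000, 0.4,
            h2_obs_1=h2_liab_1 / m1.c, h2_obs_2=h2_liab_2 / m2.c,
        )
        assert via_liab == pytest.approx(via_obs, rel=1e-12)

    def test_qt_cc_equals_cc_cc_at_same_parameters(self):
        a = var_rg_qt_cc(4000, 6000, 0.3, 0.5, h2_obs_cc=0.5)
        b = var_rg_cc_cc(4000, 6000, 0.3, h2_obs_1=0.5, h2_obs_2=0.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_qt_cc_independent_traits_value(self):
        v = var_rg_qt_cc(4000, 6000, 0.0, 0.5, h2_obs_cc=0.5)
        assert v == pytest.approx(1 / (0.25 * 2.4e7 * 2e-5), rel=1e-12)
        assert math.sqrt(v) == pytest.approx(0.0913, abs=2e-4)
        # published simulation-table analogue printed 0.093 under the
        # empirical relatedness variance: within 5%
        assert math.sqrt(v) == pytest.approx(0.093, rel=0.05)


class TestRatio:
    def test_equal_sizes_give_one(self):
        assert ratio_same_vs_diff(4000, 4000, 4000) == 1.0

    def test_arithmetic(self):
        assert ratio_same_vs_diff(4000, 1000, 3000) == pytest.approx(0.1875)

    def test_consistent_with_both_variance_formulas(self):
        n, n1, n2 = 5000, 2000, 6000
        same = var_rg_same_sample(
            BivariateDesign(mode="same_sample", n1=n, h2_1=0.4, h2_2=0.4,
                            rg=0.0, rp=0.0)
        )
        diff = var_rg_diff_samples(
            BivariateDesign(mode="different_samples", n1=n1, n2=n2,
                            h2_1=0.4, h2_2=0.4, rg=0.0)
        )
        assert same / diff == pytest.approx(ratio_same_vs_diff(n, n1, n2), rel=1e-12)
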