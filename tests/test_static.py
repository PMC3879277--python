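"""Static (acute-dose) model: Poisson lesion statistics and the LQ mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from globlekin import (
    GlobleParameters,
    acute_survival,
    class_probabilities,
    expected_lesion_counts,
    globle_from_lq,
    lambda_per_domain,
    lq_from_globle,
)


class TestLambdaAndProbabilities:
    @pytest.mark.parametrize(
        "dose, expected",
        [(0.0, 0.0), (1.0, 0.01), (100.0, 1.0)],
    )
    def test_mean_dsb_per_domain(self, defaults, dose, expected):
        assert lambda_per_domain(dose, defaults) == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rejected(self, defaults):
        with pytest.raises(ValueError, match="non-negative"):
            lambda_per_domain(-1.0, defaults)

    def test_poisson_classes_at_small_lambda(self):
        p0, p1, pm = class_probabilities(0.01)
        assert p1 == pytest.approx(0.01 * np.exp(-0.01), rel=1e-12)
        assert p0 == pytest.approx(np.exp(-0.01), rel=1e-12)

    def test_zero_lambda_is_all_undamaged(self):
        assert class_probabilities(0.0) == (1.0, 0.0, 0.0)

    @given(lam=st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_probabilities_normalized_to_machine_precision(self, lam):
        p0, p1, pm = class_probabilities(lam)
        assert abs(p0 + p1 + pm - 1.0) <= 2**-52
        assert min(p0, p1, pm) >= 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            class_probabilities(-0.1)


class TestLesionCounts:
    def test_zero_dose_no_lesions(self, defaults):
        counts = expected_lesion_counts(0.0, defaults)
        assert counts.n_i == counts.n_c == counts.l_i == counts.l_c == 0.0

    def test_isolated_count_at_one_gray(self, defaults):
        counts = expected_lesion_counts(1.0, defaults)
        assert counts.n_i == pytest.approx(3000 * 0.01 * np.exp(-0.01), rel=1e-12)
        assert counts.total == counts.l_i + counts.l_c

    def test_isolated_count_peaks_at_lambda_one(self, defaults):
        # lambda e^-lambda is maximal at lambda = 1, i.e. D = N_L/alpha_DSB
        d_peak = defaults.n_domains / defaults.dsb_yield
        n_at_peak = expected_lesion_counts(d_peak, defaults).n_i
        for d in (0.5 * d_peak, 0.9 * d_peak, 1.1 * d_peak, 2 * d_peak):
            assert expected_lesion_counts(d, defaults).n_i < n_at_peak


class TestAcuteSurvival:
    def test_zero_dose_full_survival(self, defaults):
        assert acute_survival(0.0, defaults) == 1.0

    def test_zero_lethalities_always_survive(self):
        p = GlobleParameters(eps_i=0.0, eps_c=0.0, hlt_i=0.5)
        assert acute_survival(50.0, p) == 1.0

    def test_initial_slope_is_eps_i_times_yield(self, defaults):
        h = 1e-5
        slope = -np.log(acute_survival(h, defaults)) / h
        assert slope == pytest.approx(defaults.eps_i * defaults.dsb_yield, rel=1e-5)

    @given(
        d1=st.floats(min_value=0.0, max_value=30.0),
        d2=st.floats(min_value=0.0, max_value=30.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_survival_monotone_in_dose(self, d1, d2):
        params = GlobleParameters(eps_i=0.005, eps_c=0.2, hlt_i=0.5)
        lo, hi = sorted((d1, d2))
        assert acute_survival(hi, params) <= acute_survival(lo, params)


class TestLQMapping:
    @pytest.mark.parametrize(
        "eps_i, eps_c, alpha, beta",
        [
            # printed hypothetical cell lines with alpha/beta = 1 and 14.4 Gy
            (0.00083, 0.17, 0.025, 0.025),
            (0.012, 0.19, 0.36, 0.025),
        ],
    )
    def test_forward_mapping_matches_printed_pairs(self, eps_i, eps_c, alpha, beta):
        lq = lq_from_globle(GlobleParameters(eps_i=eps_i, eps_c=eps_c, hlt_i=0.5))
        assert lq.alpha == pytest.approx(alpha, abs=5e-4)
        assert lq.beta == pytest.approx(beta, abs=5e-4)

    @pytest.mark.parametrize(
        "alpha_beta, eps_c_expected",
        [(3.0, 0.229), (8.0, 0.09)],  # pneumonitis / bone-marrow calibrations
    )
    def test_inverse_mapping_matches_endpoint_calibrations(
        self, alpha_beta, eps_c_expected
    ):
        alpha = 0.1
        eps_i, eps_c = globle_from_lq(alpha, alpha / alpha_beta)
        assert eps_i == pytest.approx(0.00333, abs=5e-6)
        assert eps_c == pytest.approx(eps_c_expected, abs=5e-4)

    def test_zero_maps_to_zero(self):
        assert globle_from_lq(0.0, 0.0) == (0.0, 0.0)

    @given(
        eps_i=st.floats(min_value=0.0, max_value=0.05),
        eps_c=st.floats(min_value=0.0, max_value=0.9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_roundtrip_identity(self, eps_i, eps_c):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = GlobleParameters(eps_i=eps_i, eps_c=eps_c, hlt_i=0.5)
        lq = lq_from_globle(p)
        try:
            back = globle_from_lq(lq.alpha, lq.beta)
        except ValueError:
            return  # negative beta from eps_c < 2 eps_i maps outside [0,1]
        assert back[0] == pytest.approx(eps_i, rel=1e-12, abs=1e-15)
        assert back[1] == pytest.approx(eps_c, rel=1e-12, abs=1e-15)

    def test_second_order_taylor_matches_beta(self, defaults):
        # central second difference of -ln S at D=0 against the analytic
        # beta; -ln S is evaluated through its closed form, which extends
        # smoothly to negative dose, allowing a true central stencil
        def neg_log_s(d):
            lam = defaults.dsb_yield * d / defaults.n_domains
            p1 = lam * np.exp(-lam)
            pm = 1.0 - np.exp(-lam) - p1
            return defaults.n_domains * (defaults.eps_i * p1 + defaults.eps_c * pm)

        h = 1e-2  # below this, subtractive cancellation dominates
        c2 = (neg_log_s(h) - 2 * neg_log_s(0.0) + neg_log_s(-h)) / (2 * h**2)
        beta = lq_from_globle(defaults).beta
        assert c2 == pytest.approx(beta, rel=1e-6)

    def test_out_of_range_inversion_reports_value(self):
        with pytest.raises(ValueError, match="eps_c"):
            globle_from_lq(0.1, 10.0)  # absurd beta drives eps_c far beyond 1


class TestParameterValidation:
    def test_eps_i_exceeding_eps_c_warns_but_allowed(self):
        with pytest.warns(UserWarning, match="eps_i"):
            GlobleParameters(eps_i=0.3, eps_c=0.1, hlt_i=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eps_i": -0.1, "eps_c": 0.2, "hlt_i": 0.5},
            {"eps_i": 0.01, "eps_c": 1.5, "hlt_i": 0.5},
            {"eps_i": 0.01, "eps_c": 0.2, "hlt_i": 0.0},
            {"eps_i": 0.01, "eps_c": 0.2, "hlt_i": 0.5, "dsb_yield": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GlobleParameters(**kwargs)
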