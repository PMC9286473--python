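import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from seapump.attenuation import (SeasonalAttenuation, equivalent_b, martin_flux,
                                 martin_te, mean_A, seasonal_A, seasonal_b,
                                 sinking_coefficient, sinking_speed,
                                 transit_time)

P60 = SeasonalAttenuation.from_fraction(frac=0.6)  # b_ref 1.388, 60% amplitude


class TestMartinFlux:
    def test_identity_at_reference(self):
        assert martin_flux(3.0, 120.0, 120.0, 1.388) == pytest.approx(3.0)

    def test_no_attenuation(self):
        assert martin_flux(3.0, 120.0, 4000.0, 0.0) == pytest.approx(3.0)

    def test_printed_value(self):
        assert martin_flux(1.0, 120.0, 1080.0, 1.388) == pytest.approx(0.047, abs=5e-4)

    def test_shallower_than_reference_rejected(self):
        with pytest.raises(ValueError):
            martin_flux(1.0, 120.0, 100.0, 1.0)

    def test_strictly_decreasing_in_depth(self):
        z = np.linspace(120.0, 5000.0, 200)
        f = martin_flux(1.0, 120.0, z, 1.388)
        assert np.all(np.diff(f) < 0)


class TestMartinTE:
    @pytest.mark.parametrize("b,expected,tol", [
        (1.110, 0.088, 1.5e-3),  # printed as 0.088; exact value 0.0873
        (2.221, 0.0076, 5e-5),
        (0.0, 1.0, 1e-15),
    ])
    def test_values(self, b, expected, tol):
        assert martin_te(b) == pytest.approx(expected, abs=tol)

    def test_reference_case(self):
        assert martin_te(1.388) == pytest.approx(0.047, abs=5e-4)

    def test_strictly_decreasing_in_b(self):
        b = np.linspace(0.0, 3.0, 100)
        te = martin_te(b)
        assert np.all(np.diff(te) < 0)

    def test_bad_depths_rejected(self):
        with pytest.raises(ValueError):
            martin_te(1.0, z0=500.0, z1=100.0)


class TestSinkingCoefficient:
    @pytest.mark.parametrize("b,expected", [
        (1.388, 0.036), (2.221, 0.023), (0.555, 0.090),
    ])
    def test_printed_values(self, b, expected):
        assert sinking_coefficient(0.05, b) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError):
            sinking_coefficient(0.05, 0.0)


class TestSeasonalB:
    def test_equator_is_reference(self):
        for t in (0.0, 33.0, 190.0):
            for theta in (0.0, 3.0, 6.0, 9.0):
                p = SeasonalAttenuation.from_fraction(frac=0.6, theta=theta)
                assert seasonal_b(t, 0.0, p) == pytest.approx(p.b_ref)

    def test_zero_amplitude(self):
        p = SeasonalAttenuation(delta_b=0.0)
        t = np.linspace(0, 360, 37)
        assert np.allclose(seasonal_b(t, 50.0, p), p.b_ref)

    def test_range_endpoints(self):
        t = np.linspace(0, 360, 100000)
        b = seasonal_b(t, 45.0, P60)
        assert b.min() == pytest.approx(0.555, abs=5e-4)
        assert b.max() == pytest.approx(2.221, abs=5e-4)

    def test_amplitude_validation(self):
        with pytest.raises(ValueError):
            SeasonalAttenuation(b_ref=1.0, delta_b=1.5)

    @settings(deadline=None, max_examples=40)
    @given(theta=st.floats(0, 12), phi=st.floats(-90, 90).filter(lambda x: abs(x) > 1e-6),
           frac=st.floats(0, 0.99))
    def test_annual_mean_is_b_ref(self, theta, phi, frac):
        p = SeasonalAttenuation.from_fraction(frac=frac, theta=theta)
        val, _ = quad(lambda t: seasonal_b(t, phi, p), 0, p.period, limit=100)
        assert val / p.period == pytest.approx(p.b_ref, rel=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(t=st.floats(0, 360), phi=st.floats(0.1, 90), theta=st.floats(0, 12))
    def test_hemisphere_flip_is_six_month_shift(self, t, phi, theta):
        p = SeasonalAttenuation.from_fraction(frac=0.6, theta=theta)
        p_shift = SeasonalAttenuation.from_fraction(frac=0.6, theta=(theta + 6) % 12)
        assert seasonal_b(t, phi, p) == pytest.approx(
            seasonal_b(t, -phi, p_shift), rel=1e-12)


class TestSeasonalA:
    def test_extrema_60pct(self):
        t = np.linspace(0, 360, 100000)
        A = seasonal_A(t, 45.0, P60)
        assert A.min() == pytest.approx(0.023, abs=5e-4)
        assert A.max() == pytest.approx(0.090, abs=5e-4)

    def test_extrema_20pct(self):
        p = SeasonalAttenuation.from_fraction(frac=0.2)
        t = np.linspace(0, 360, 100000)
        A = seasonal_A(t, 45.0, p)
        assert A.min() == pytest.approx(0.030, abs=5e-4)
        assert A.max() == pytest.approx(0.045, abs=5e-4)

    def test_constant_when_no_seasonality(self):
        p = SeasonalAttenuation(delta_b=0.0)
        t = np.linspace(0, 360, 50)
        assert np.allclose(seasonal_A(t, 45.0, p), p.lam / p.b_ref)

    def test_degenerate_amplitude_rejected(self):
        p = SeasonalAttenuation(b_ref=1.0, delta_b=1.0)
        with pytest.raises(ValueError):
            seasonal_A(0.0, 45.0, p)


class TestMeanA:
    def test_printed_value(self):
        assert mean_A(P60) == pytest.approx(0.045, abs=5e-4)

    def test_no_seasonality(self):
        p = SeasonalAttenuation(delta_b=0.0)
        assert mean_A(p) == pytest.approx(p.lam / p.b_ref, rel=1e-14)

    @settings(deadline=None, max_examples=25)
    @given(frac=st.floats(0, 0.95), theta=st.floats(0, 12))
    def test_closed_form_matches_quadrature(self, frac, theta):
        p = SeasonalAttenuation.from_fraction(frac=frac, theta=theta)
        val, _ = quad(lambda t: seasonal_A(t, 45.0, p), 0, p.period, limit=200)
        assert mean_A(p) == pytest.approx(val / p.period, rel=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(frac=st.floats(0, 0.95))
    def test_jensen_inequality(self, frac):
        p = SeasonalAttenuation.from_fraction(frac=frac)
        assert mean_A(p) >= p.lam / p.b_ref - 1e-15
        if frac > 1e-6:
            assert mean_A(p) > p.lam / p.b_ref


class TestEquivalentB:
    def test_printed_value(self):
        assert equivalent_b(P60) == pytest.approx(1.110, abs=5e-4)

    def test_no_seasonality(self):
        p = SeasonalAttenuation(delta_b=0.0)
        assert equivalent_b(p) == pytest.approx(p.b_ref, rel=1e-14)

    def test_20pct_matches_quadrature(self):
        p = SeasonalAttenuation.from_fraction(frac=0.2)
        val, _ = quad(lambda t: seasonal_A(t, 45.0, p), 0, p.period, limit=200)
        assert equivalent_b(p) == pytest.approx(p.lam / (val / p.period), rel=1e-9)


class TestSinkingSpeed:
    def test_constant_b_at_120m(self):
        p = SeasonalAttenuation(delta_b=0.0)
        assert sinking_speed(120.0, 0.0, 45.0, p) == pytest.approx(4.32, abs=5e-3)

    def test_seasonal_range_at_120m(self):
        t = np.linspace(0, 360, 100000)
        w = sinking_speed(120.0, t, 45.0, P60)
        assert w.min() == pytest.approx(2.70, abs=5e-3)
        assert w.max() == pytest.approx(10.81, abs=5e-3)

    def test_seasonal_range_at_1080m(self):
        t = np.linspace(0, 360, 100000)
        w = sinking_speed(1080.0, t, 45.0, P60)
        # printed values were computed from b rounded to 0.555/2.221
        assert w.min() == pytest.approx(24.31, abs=0.02)
        assert w.max() == pytest.approx(97.30, abs=0.04)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            sinking_speed(-1.0, 0.0, 45.0, P60)


class TestTransitTime:
    def test_mesopelagic_61_days(self):
        assert transit_time(120.0, 1080.0, 0.05 / 1.388) == pytest.approx(61, abs=0.5)

    def test_deep_43_days(self):
        assert transit_time(1080.0, 5000.0, 0.05 / 1.388) == pytest.approx(43, abs=0.5)

    def test_extreme_b_values(self):
        assert transit_time(120.0, 1080.0, 0.05 / 0.555) == pytest.approx(24, abs=0.5)
        # 97.6 days exactly; printed as "97" (truncated)
        assert transit_time(120.0, 1080.0, 0.05 / 2.221) == pytest.approx(97, abs=1.0)

    def test_zero_start_rejected(self):
        with pytest.raises(ValueError):
            transit_time(0.0, 1080.0, 0.036)


class TestLambdaSeasonalVariants:
    def test_constant_a_preset_has_constant_A(self):
        p = SeasonalAttenuation.constant_a_preset(frac=0.6)
        t = np.linspace(0, 360, 500)
        A = seasonal_A(t, 45.0, p)
        assert np.allclose(A, p.lam / p.b_ref, rtol=1e-12)

    def test_lambda_varying_preset_keeps_b_constant(self):
        p = SeasonalAttenuation.lambda_varying_preset(frac=0.5)
        t = np.linspace(0, 360, 50)
        assert np.allclose(seasonal_b(t, 45.0, p), p.b_ref)
        A = seasonal_A(t, 45.0, p)
        assert A.max() > A.min()  # A still varies through lambda

    def test_mean_A_quadrature_fallback(self):
        p = SeasonalAttenuation.lambda_varying_preset(frac=0.5)
        # lambda oscillation averages out exactly: mean A = lam / b_ref
        assert mean_A(p) == pytest.approx(p.lam / p.b_ref, rel=1e-9)
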