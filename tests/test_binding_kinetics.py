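"""Isotherm, mass-action ODE and receptor frequency-response behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import preqsense as pq
from preqsense import (
    DomainError,
    ReceptorKinetics,
    SaturationError,
    corner_frequency,
    inverse_langmuir,
    langmuir_fraction,
    measure_amplitude_phase,
    measure_corner_frequency,
    measure_normalized_amplitude,
    receptor_frequency_response,
    simulate_binding,
)
from preqsense.waveforms import Constant, make_sinusoid, make_step_train


class TestLangmuir:
    @pytest.mark.parametrize(
        "t_over_kd, expected",
        [(1.0, 0.5), (0.0, 0.0), (0.1, 0.1 / 1.1)],
    )
    def test_isotherm_values(self, insulin_kin, t_over_kd, expected):
        assert langmuir_fraction(t_over_kd * insulin_kin.k_d, insulin_kin) == pytest.approx(expected)

    def test_half_saturation_at_one_tenth_kd_rounds_to_0_091(self, insulin_kin):
        assert langmuir_fraction(0.1 * insulin_kin.k_d, insulin_kin) == pytest.approx(0.091, abs=5e-4)

    def test_negative_concentration_rejected(self, insulin_kin):
        with pytest.raises(DomainError):
            langmuir_fraction(-1e-12, insulin_kin)

    def test_inverse_examples(self):
        kin = ReceptorKinetics.from_kd(1e6, 500e-12)
        assert inverse_langmuir(0.5, kin) == pytest.approx(kin.k_d)
        assert inverse_langmuir(0.0, kin) == 0.0
        assert inverse_langmuir(1 / 6, kin) == pytest.approx(100e-12)

    def test_inverse_saturation_and_clamp(self, insulin_kin):
        with pytest.raises(SaturationError):
            inverse_langmuir(1.0, insulin_kin)
        assert inverse_langmuir(-0.01, insulin_kin) == 0.0
        with pytest.raises(DomainError):
            inverse_langmuir(-0.01, insulin_kin, strict=True)

    @given(y=st.floats(min_value=0.0, max_value=0.999))
    @settings(deadline=None, max_examples=50)
    def test_inverse_is_exact_inverse(self, y):
        kin = ReceptorKinetics(k_on=1e6, k_off=5e-4)
        assert langmuir_fraction(inverse_langmuir(y, kin), kin) == pytest.approx(y, abs=1e-12)

    @given(t1=st.floats(min_value=1e-13, max_value=1e-7),
           t2=st.floats(min_value=1e-13, max_value=1e-7))
    @settings(deadline=None, max_examples=50)
    def test_isotherm_monotone(self, t1, t2):
        kin = ReceptorKinetics(k_on=1e6, k_off=5e-4)
        lo, hi = sorted([t1, t2])
        assert langmuir_fraction(lo, kin) <= langmuir_fraction(hi, kin) < 1.0


class TestCornerFrequency:
    def test_insulin_case_study(self, insulin_kin):
        omega_c = corner_frequency(insulin_kin, 100e-12)
        assert omega_c == pytest.approx(6e-4)
        assert 2 * np.pi / omega_c / 3600 == pytest.approx(2.9, abs=0.1)  # ~3 h period

    def test_limits(self, insulin_kin):
        assert corner_frequency(insulin_kin, 0.0) == insulin_kin.k_off
        assert corner_frequency(insulin_kin, insulin_kin.k_d) == pytest.approx(2 * insulin_kin.k_off)


class TestFrequencyResponse:
    def test_dc_point(self, insulin_kin):
        fr = receptor_frequency_response(insulin_kin, 100e-12, 0.0)
        assert fr.normalized_magnitude == pytest.approx(1.0)
        assert fr.phase_lag_deg == pytest.approx(0.0)
        assert fr.gain.imag == 0.0

    def test_minus_3db_at_corner(self, insulin_kin):
        omega_c = corner_frequency(insulin_kin, 100e-12)
        fr = receptor_frequency_response(insulin_kin, 100e-12, omega_c)
        assert fr.normalized_magnitude == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert fr.phase_lag_deg == pytest.approx(45.0)

    def test_insulin_ten_minute_attenuation(self, insulin_kin):
        # 10-min period: ~20-fold attenuation; 1-h period: ~3-fold
        for period, factor in [(600.0, 17.5), (3600.0, 3.1)]:
            fr = receptor_frequency_response(insulin_kin, 100e-12, 2 * np.pi / period)
            assert 1 / fr.normalized_magnitude == pytest.approx(factor, rel=0.01)

    def test_variants_differ_by_one_minus_c0(self, insulin_kin):
        t0 = 10 * insulin_kin.k_d  # high TOP where the variants diverge
        printed = receptor_frequency_response(insulin_kin, t0, 1e-3, "printed")
        lin = receptor_frequency_response(insulin_kin, t0, 1e-3, "linearized")
        c0 = langmuir_fraction(t0, insulin_kin)
        assert lin.magnitude / printed.magnitude == pytest.approx(1 - c0)
        assert lin.normalized_gain == printed.normalized_gain

    def test_magnitude_non_increasing(self, insulin_kin):
        omegas = np.logspace(-6, 0, 30)
        mags = [receptor_frequency_response(insulin_kin, 1e-10, w).normalized_magnitude
                for w in omegas]
        assert np.all(np.diff(mags) <= 0)


class TestSimulateBinding:
    def test_constant_input_fixed_point(self, insulin_kin):
        t0 = 100e-12
        y_eq = langmuir_fraction(t0, insulin_kin)
        t = np.linspace(0, 5000, 500)
        series = simulate_binding(insulin_kin, Constant(t0), y_eq, t)
        assert np.allclose(series.y, y_eq, atol=1e-10)

    def test_pure_dissociation_is_exponential(self, insulin_kin):
        t = np.linspace(0, 3 / insulin_kin.k_off, 300)
        series = simulate_binding(insulin_kin, Constant(0.0), 0.5, t)
        assert np.allclose(series.y, 0.5 * np.exp(-insulin_kin.k_off * t), atol=1e-10)

    def test_converges_to_isotherm_from_any_start(self, unit_kin):
        wf = Constant(0.7)
        k_eq = unit_kin.k_on * 0.7 + unit_kin.k_off
        t = np.linspace(0, 25 / k_eq, 200)
        for y0 in (0.0, 1.0):
            series = simulate_binding(unit_kin, wf, y0, t)
            assert abs(series.y[-1] - langmuir_fraction(0.7, unit_kin)) < 1e-6

    def test_exact_exponential_matches_generic_integrator(self, mab1_kin):
        steps = [(20e-9, 300.0), (0.0, 300.0)]
        wf = make_step_train(steps)
        t = np.linspace(0, 600, 1201)
        exact = simulate_binding(mab1_kin, wf, 0.0, t)

        class _Opaque:  # same waveform without the piecewise-constant flag
            is_piecewise_constant = False
            period = None

            def __call__(self, tt):
                return wf(tt)

        generic = simulate_binding(mab1_kin, _Opaque(), 0.0, t)
        assert np.max(np.abs(exact.y - generic.y)) < 1e-8

    def test_negative_waveform_rejected(self, insulin_kin):
        class Bad:
            is_piecewise_constant = False
            period = None

            def __call__(self, t):
                return np.full(np.shape(t), -1e-12)

        with pytest.raises(DomainError):
            simulate_binding(insulin_kin, Bad(), 0.0, np.linspace(0, 10, 20))

    def test_sinusoid_mean_matches_c0(self, unit_kin):
        # TOP = 0.1 and T_1/T_0 = 1/3: mean fraction bound ~ 0.091
        t_0 = 0.1 * unit_kin.k_d
        omega_c = corner_frequency(unit_kin, t_0)
        f = omega_c / (2 * np.pi)
        settle = 10 / omega_c
        t = np.linspace(0, settle + 4 / f, 6000)
        wf = make_sinusoid(t_0, t_0 / 3, f)
        series = simulate_binding(unit_kin, wf, langmuir_fraction(t_0, unit_kin), t)
        # average over an integer number of periods past the transient
        mask = (series.t >= settle) & (series.t <= settle + 4 / f)
        mean = np.trapezoid(series.y[mask], series.t[mask]) / (series.t[mask][-1] - series.t[mask][0])
        assert mean == pytest.approx(0.091, abs=1e-3)


class TestAmplitudePhaseMeasurement:
    def test_pure_sinusoid_recovered_exactly(self):
        t = np.linspace(0, 100, 5000)
        f = 0.25
        series = pq.BoundFractionSeries(t=t, y=0.1 + 0.01 * np.cos(2 * np.pi * f * t))
        amp, phase = measure_amplitude_phase(series, f, settle=0.0)
        assert amp == pytest.approx(0.01, rel=1e-9)
        assert phase == pytest.approx(0.0, abs=1e-7)

    def test_window_too_short(self):
        t = np.linspace(0, 1, 100)
        series = pq.BoundFractionSeries(t=t, y=np.full(100, 0.5))
        with pytest.raises(ValueError):
            measure_amplitude_phase(series, f=0.5, settle=0.0)

    def test_simulated_response_at_corner(self, unit_kin):
        # Omega_T = Omega_C with T_1/T_0 = 1/3 at TOP 0.1: -3 dB and 45 degrees
        t_0 = 0.1 * unit_kin.k_d
        omega_c = corner_frequency(unit_kin, t_0)
        amp, phase = measure_normalized_amplitude(unit_kin, t_0, t_0 / 3, omega_c)
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.02)
        assert phase == pytest.approx(45.0, abs=1.0)

    @pytest.mark.parametrize("ratio", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_low_pass_model_within_2pct_small_signal(self, unit_kin, ratio):
        t_0 = 0.1 * unit_kin.k_d
        omega_c = corner_frequency(unit_kin, t_0)
        amp, _ = measure_normalized_amplitude(unit_kin, t_0, 0.1 * t_0, ratio * omega_c)
        assert amp == pytest.approx(1 / np.sqrt(1 + ratio**2), rel=0.02)

    def test_rolloff_slope_minus_20db_per_decade(self, unit_kin):
        t_0 = 0.1 * unit_kin.k_d
        omega_c = corner_frequency(unit_kin, t_0)
        a10, _ = measure_normalized_amplitude(unit_kin, t_0, 0.1 * t_0, 10 * omega_c)
        a100, _ = measure_normalized_amplitude(unit_kin, t_0, 0.1 * t_0, 100 * omega_c)
        slope = 20 * np.log10(a100 / a10)  # dB over one decade
        assert slope == pytest.approx(-20.0, rel=0.05)


class TestCornerFrequencyMeasurement:
    @pytest.mark.parametrize("top, expected_ratio", [(0.01, 1.01), (0.1, 1.1), (1.0, 2.0), (10.0, 11.0)])
    def test_recovers_analytic_corner_small_signal(self, unit_kin, top, expected_ratio):
        t_0 = top * unit_kin.k_d
        measured = measure_corner_frequency(unit_kin, t_0, 0.1 * t_0)
        assert measured / unit_kin.k_off == pytest.approx(expected_ratio, rel=0.05)

    def test_large_oscillation_near_saturation_deviates(self, unit_kin):
        # At high TOP with T_1 -> T_0 the sensor saturates and the small-signal
        # expression no longer applies: the error exceeds the small-signal one.
        t_0 = 10 * unit_kin.k_d
        small = measure_corner_frequency(unit_kin, t_0, 0.05 * t_0, span_decades=2.0)
        large = measure_corner_frequency(unit_kin, t_0, 0.95 * t_0, span_decades=2.0)
        err_small = abs(small / unit_kin.k_off - 11.0) / 11.0
        err_large = abs(large / unit_kin.k_off - 11.0) / 11.0
        assert err_large > err_small
        assert err_large > 0.05


class TestSeriesCsv:
    def test_round_trip_12_digits(self, tmp_path, insulin_kin):
        t = np.linspace(0, 600, 61)
        series = simulate_binding(insulin_kin, Constant(1e-10), 0.0, t)
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = pq.BoundFractionSeries.from_csv(path)
        assert np.allclose(back.y, series.y, rtol=1e-11, atol=0)
        assert np.allclose(back.t, series.t, rtol=1e-11, atol=0)
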