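"""Arterial flow summation and cycle integration."""

import numpy as np
import pytest

from craniospinal.exceptions import PeriodMismatchError
from craniospinal.flow_volume import FlowCurve, delta_v_art, sum_arterial_flows, volume_curve

from conftest import make_flow


class TestSumArterialFlows:
    def test_constant_curves_add(self):
        curves = [make_flow(np.full(32, 142.0), 0.845) for _ in range(3)]
        total = sum_arterial_flows(*curves)
        np.testing.assert_allclose(total.values_ml_per_s * 60.0, 426.0)
        assert total.mean_flow_ml_per_min == pytest.approx(426.0)

    def test_zero_curves_are_identity(self):
        rng = np.random.default_rng(0)
        q = make_flow(400 + 50 * rng.standard_normal(32), 0.8)
        zero = make_flow(np.zeros(32), 0.8)
        total = sum_arterial_flows(q, zero, zero)
        np.testing.assert_array_equal(total.values_ml_per_s, q.values_ml_per_s)

    def test_clamp_negative_zeroes_contribution(self):
        values = np.full(32, 100.0)
        values[5] = -5.0
        clamped = sum_arterial_flows(make_flow(values, 0.8),
                                     make_flow(np.zeros(32), 0.8),
                                     make_flow(np.zeros(32), 0.8),
                                     clamp_negative=True)
        assert clamped.values_ml_per_s[5] == 0.0
        unclamped = sum_arterial_flows(make_flow(values, 0.8),
                                       make_flow(np.zeros(32), 0.8),
                                       make_flow(np.zeros(32), 0.8))
        assert unclamped.values_ml_per_s[5] == pytest.approx(-5.0 / 60.0)

    def test_period_mismatch_rejected(self):
        with pytest.raises(PeriodMismatchError):
            sum_arterial_flows(make_flow(np.ones(32), 0.80),
                               make_flow(np.ones(32), 0.80),
                               make_flow(np.ones(32), 0.90))

    def test_vessel_order_irrelevant(self):
        rng = np.random.default_rng(1)
        curves = [make_flow(300 + 100 * rng.standard_normal(32), 0.9) for _ in range(3)]
        ref = sum_arterial_flows(*curves).values_ml_per_s
        for perm in ((1, 2, 0), (2, 0, 1), (0, 2, 1)):
            permuted = sum_arterial_flows(*[curves[i] for i in perm]).values_ml_per_s
            np.testing.assert_allclose(permuted, ref, rtol=1e-12)


def dense_amplitude(q_func, period, subtract_mean, n=100_000):
    """Dense-quadrature oracle for the volume-curve amplitude."""
    t = np.linspace(0.0, period, n, endpoint=False)
    y = q_func(t)
    if subtract_mean:
        y = y - np.mean(y)
    v = np.concatenate([[0.0], np.cumsum(y) * (period / n)])
    return np.max(v) - np.min(v)


class TestVolumeCurve:
    def test_constant_flow_closed_form(self):
        q = make_flow(np.full(32, 426.0), 0.845)
        v = volume_curve(q)
        assert v.delta_v_art_ml == pytest.approx((426.0 / 60.0) * 0.845, rel=1e-14)
        # non-decreasing for positive flow without mean subtraction
        assert np.all(np.diff(np.append(v.values_ml, v.closing_value_ml)) >= 0)

    def test_constant_flow_mean_subtracted_is_flat(self):
        v = volume_curve(make_flow(np.full(32, 426.0), 0.845), subtract_mean=True)
        assert v.delta_v_art_ml == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_mean_subtracted_matches_antiderivative(self):
        period = 1.0
        t32 = np.arange(32) / 32 * period
        q = make_flow(420 + 300 * np.sin(2 * np.pi * t32 / period), period)
        v = volume_curve(q, subtract_mean=True)
        analytic = 5.0 * period / np.pi          # A*T/pi with A = 300/60 mL/s
        assert v.delta_v_art_ml == pytest.approx(analytic, rel=0.01)
        oracle = dense_amplitude(
            lambda t: (420 + 300 * np.sin(2 * np.pi * t / period)) / 60.0, period, True)
        assert v.delta_v_art_ml == pytest.approx(oracle, rel=0.01)

    def test_sinusoid_without_subtraction_is_total_integral(self):
        period = 1.0
        t32 = np.arange(32) / 32 * period
        q = make_flow(420 + 300 * np.sin(2 * np.pi * t32 / period), period)
        v = volume_curve(q, subtract_mean=False)
        assert v.delta_v_art_ml == pytest.approx(7.0, rel=1e-12)

    def test_positive_flow_amplitude_equals_mean_times_period(self):
        rng = np.random.default_rng(7)
        values = 200 + 150 * rng.random(32)       # strictly positive
        q = make_flow(values, 0.77)
        v = volume_curve(q)
        assert v.delta_v_art_ml == pytest.approx(np.mean(q.values_ml_per_s) * 0.77, rel=1e-13)

    def test_mean_subtracted_amplitude_offset_invariant(self):
        rng = np.random.default_rng(8)
        values = 100 * rng.standard_normal(32)
        a = volume_curve(make_flow(values, 0.9), subtract_mean=True).delta_v_art_ml
        b = volume_curve(make_flow(values + 5000.0, 0.9), subtract_mean=True).delta_v_art_ml
        assert a == pytest.approx(b, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("subtract_mean", [False, True])
    def test_32_point_quadrature_close_to_dense_oracle(self, seed, subtract_mean):
        """Band-limited waveforms (<= 4 harmonics): 32 samples suffice to <2%."""
        rng = np.random.default_rng(seed)
        period = rng.uniform(0.6, 1.1)
        # physiological harmonic decay: fundamental dominates, no cancellation
        amps = rng.uniform(40, 80, size=4) / np.arange(1, 5)
        phases = rng.uniform(0, 2 * np.pi, size=4)

        def q_ml_min(t):
            y = np.full_like(t, 400.0)
            for k, (a, ph) in enumerate(zip(amps, phases), start=1):
                y = y + a * np.sin(2 * np.pi * k * t / period + ph)
            return y

        t32 = np.arange(32) / 32 * period
        v = volume_curve(make_flow(q_ml_min(t32), period), subtract_mean=subtract_mean)
        oracle = dense_amplitude(lambda t: q_ml_min(t) / 60.0, period, subtract_mean)
        assert v.delta_v_art_ml == pytest.approx(oracle, rel=0.02)


class TestDeltaVArt:
    def test_amplitudes(self):
        ramp = volume_curve(make_flow(np.full(32, 7.0 / 0.845 * 60.0), 0.845))
        assert delta_v_art(ramp) == pytest.approx(7.0, rel=1e-12)
        t32 = np.arange(32) / 32
        cosine = volume_curve(make_flow(300 * np.cos(2 * np.pi * t32), 1.0), subtract_mean=True)
        assert delta_v_art(cosine) == pytest.approx(2 * 5.0 / (2 * np.pi), rel=0.01)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            FlowCurve(np.array([np.nan] * 32), 0.8)
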