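"""Baseline ICP pulse chain: selection, filtering, segmentation, averaging."""

import numpy as np
import pytest

from craniospinal import AnalysisConfig
from craniospinal.exceptions import BaselineTooShortError, NoCardiacPeakError, TooFewPulsesError
from craniospinal.icp_pulse import (
    ICPSegment,
    average_pulse,
    estimate_cardiac_frequency,
    extract_average_pulse,
    fft_bandpass,
    segment_pulses,
    select_baseline,
)

from conftest import make_icp

FS = 100.0


def tone_segment(duration_s, components, dc=0.0, noise_sd=0.0, seed=0, fs=FS):
    """Segment built from (amplitude, frequency) sinusoids plus optional noise."""
    t = np.arange(int(duration_s * fs)) / fs
    x = np.full_like(t, dc)
    for amp, freq in components:
        x = x + amp * np.sin(2 * np.pi * freq * t)
    if noise_sd:
        x = x + noise_sd * np.random.default_rng(seed).standard_normal(len(t))
    return ICPSegment(x, fs)


class TestSelectBaseline:
    def test_window_ends_gap_before_infusion(self):
        rec = make_icp(np.arange(31000) / FS, baseline_end=300.0, infusion_start=300.0)
        seg = select_baseline(rec, window_s=30.0, gap_s=10.0)
        # samples from t in [260, 290)
        assert seg.values_mmHg[0] == pytest.approx(260.0)
        assert len(seg.values_mmHg) == 3000

    def test_short_baseline_falls_back_with_warning(self, caplog):
        rec = make_icp(np.zeros(4000), baseline_end=20.0, infusion_start=20.0)
        with caplog.at_level("WARNING"):
            seg = select_baseline(rec, window_s=30.0, gap_s=10.0)
        assert seg.duration_s == pytest.approx(20.0)
        assert any("shorter" in m for m in caplog.messages)

    def test_too_short_baseline_errors(self):
        rec = make_icp(np.zeros(1500), baseline_end=5.0, infusion_start=5.0)
        with pytest.raises(BaselineTooShortError):
            select_baseline(rec)


class TestCardiacFrequency:
    def test_pure_tone_within_one_bin(self):
        seg = tone_segment(30.0, [(1.5, 1.2)])
        assert estimate_cardiac_frequency(seg) == pytest.approx(1.2, abs=1.0 / 30.0)

    def test_respiration_outside_band_ignored(self):
        seg = tone_segment(30.0, [(1.5, 1.2), (3.0, 0.25)], dc=12.0)
        assert estimate_cardiac_frequency(seg) == pytest.approx(1.2, abs=1.0 / 30.0)

    def test_flat_signal_has_no_peak(self):
        seg = ICPSegment(np.full(3000, 12.0), FS)
        with pytest.raises(NoCardiacPeakError):
            estimate_cardiac_frequency(seg)


class TestFftBandpass:
    def test_in_band_tone_and_dc_preserved(self):
        seg = tone_segment(30.0, [(1.5, 1.2)], dc=12.0)
        out = fft_bandpass(seg, 1.2)
        np.testing.assert_allclose(out.values_mmHg, seg.values_mmHg, atol=0.01 * 1.5)

    def test_out_of_band_respiration_removed(self):
        # integer-cycle tones (36 and 6 cycles in 30 s) keep spectra leakage-free
        clean = tone_segment(30.0, [(1.5, 1.2)], dc=12.0)
        noisy = tone_segment(30.0, [(1.5, 1.2), (3.0, 0.2)], dc=12.0)
        out = fft_bandpass(noisy, 1.2)
        resp_in = noisy.values_mmHg - clean.values_mmHg
        resp_out = out.values_mmHg - clean.values_mmHg
        assert np.sum(resp_out**2) < 1e-3 * np.sum(resp_in**2)
        # Parseval bookkeeping: power outside the keep band is entirely removed
        spectrum = np.fft.rfft(out.values_mmHg)
        freqs = np.fft.rfftfreq(len(out.values_mmHg), d=1.0 / FS)
        out_of_band = (freqs > 0) & ((freqs < 0.66 * 1.2) | (freqs > 12.0))
        assert np.sum(np.abs(spectrum[out_of_band]) ** 2) < 1e-3 * np.sum(resp_in**2)

    def test_drop_dc_zeroes_mean(self):
        seg = tone_segment(30.0, [(1.5, 1.2)], dc=12.0)
        out = fft_bandpass(seg, 1.2, AnalysisConfig(keep_dc=False))
        assert np.mean(out.values_mmHg) == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        seg = tone_segment(30.0, [(1.5, 1.2), (3.0, 0.25)], dc=12.0, noise_sd=0.3)
        once = fft_bandpass(seg, 1.2)
        twice = fft_bandpass(once, 1.2)
        np.testing.assert_allclose(twice.values_mmHg, once.values_mmHg, atol=1e-9)


def brute_force_peaks(x, min_gap):
    """Oracle: strict local maxima, greedily thinned to the minimum gap."""
    candidates = [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] >= x[i + 1]]
    kept = []
    for i in sorted(candidates, key=lambda i: -x[i]):
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    return sorted(kept)


class TestSegmentPulses:
    def test_sinusoid_pulse_count(self):
        seg = tone_segment(30.0, [(1.5, 1.2)], dc=12.0)
        pulses = segment_pulses(seg, 1.2)
        assert len(pulses) == 35          # floor(30 * 1.2) - 1 complete spans
        oracle = brute_force_peaks(seg.values_mmHg, int(0.6 / 1.2 * FS))
        assert len(pulses) == len(oracle) - 1

    def test_ectopic_length_beat_discarded(self):
        # 28 normal beats of 1 s, one 40%-longer beat spliced in the middle
        beat = 12.0 + 1.5 * np.cos(2 * np.pi * np.arange(100) / 100)
        long_beat = 12.0 + 1.5 * np.cos(2 * np.pi * np.arange(140) / 140)
        x = np.concatenate([np.tile(beat, 14), long_beat, np.tile(beat, 14)])
        pulses = segment_pulses(ICPSegment(x, FS), 1.0)
        normal = segment_pulses(ICPSegment(np.tile(beat, 29), FS), 1.0)
        assert len(pulses) == len(normal) - 1

    def test_flat_signal_has_too_few_pulses(self):
        with pytest.raises(TooFewPulsesError):
            segment_pulses(ICPSegment(np.full(3000, 12.0), FS), 1.2)


class TestAveragePulse:
    def test_identical_pulses_average_to_themselves(self):
        pulse = 12.0 + 1.5 * np.cos(2 * np.pi * np.arange(90) / 90)
        avg = average_pulse([pulse.copy() for _ in range(8)], FS)
        grid = np.interp(np.arange(32) / 32, np.append(np.arange(90) / 90, 1.0),
                         np.append(pulse, pulse[0]))
        np.testing.assert_allclose(avg.values_mmHg, grid, rtol=1e-12)
        assert avg.period_s == pytest.approx(0.9)
        assert avg.n_beats == 8

    def test_sinusoid_beats_recover_peak_to_peak(self):
        pulse = 12.0 + 1.5 * np.cos(2 * np.pi * np.arange(84) / 84)
        avg = average_pulse([pulse.copy() for _ in range(10)], FS)
        assert avg.delta_p_cc_mmHg == pytest.approx(3.0, rel=0.02)

    def test_averaging_reduces_noise_as_sqrt_n(self):
        # the residual SD after averaging n noisy beats must scale as 1/sqrt(n)
        rng = np.random.default_rng(3)
        base = 12.0 + 1.5 * np.cos(2 * np.pi * np.arange(100) / 100)
        sigma = 0.5
        reference = average_pulse([base, base, base], FS).values_mmHg

        def residual_sd(n_beats):
            reps = [
                average_pulse([base + sigma * rng.standard_normal(100)
                               for _ in range(n_beats)], FS)
                for _ in range(300)
            ]
            return np.std(np.array([p.values_mmHg for p in reps]) - reference)

        assert residual_sd(4) / residual_sd(16) == pytest.approx(2.0, rel=0.1)


class TestEndToEnd:
    def test_synthetic_baseline_recovers_cardiac_amplitude(self):
        rec = make_icp(
            tone_segment(310.0, [(1.5, 1.2), (2.0, 0.25)], dc=12.0,
                         noise_sd=0.1, seed=5).values_mmHg,
            baseline_end=300.0, infusion_start=300.0,
        )
        pulse = extract_average_pulse(rec)
        assert pulse.delta_p_cc_mmHg == pytest.approx(3.0, rel=0.05)
        assert pulse.period_s == pytest.approx(1 / 1.2, rel=0.02)

    def test_amplitude_invariant_to_constant_offset(self):
        x = tone_segment(310.0, [(1.5, 1.2)], dc=12.0, noise_sd=0.05, seed=6).values_mmHg
        rec = make_icp(x, baseline_end=300.0, infusion_start=300.0)
        shifted = make_icp(x + 25.0, baseline_end=300.0, infusion_start=300.0)
        a = extract_average_pulse(rec).delta_p_cc_mmHg
        b = extract_average_pulse(shifted).delta_p_cc_mmHg
        assert a == pytest.approx(b, rel=1e-9)
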