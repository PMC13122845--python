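"""Baseline ICP pulse extraction.

The craniospinal pressure change over one cardiac cycle (``dP_CC``) is the
peak-to-peak amplitude of an ensemble-averaged ICP pulse taken from a short
baseline window recorded shortly before the infusion starts:

1. select a baseline window (default 30 s, ending 10 s before infusion);
2. locate the cardiac fundamental as the dominant spectral peak in the
   48-150 BPM band;
3. remove respiration and broadband noise with an FFT band filter that keeps
   the cardiac fundamental and its harmonics (and, by default, the mean);
4. detect beat peaks, cut the signal into single pulses, discard beats of
   outlying length;
5. resample each pulse onto a normalized 32-point cycle, average pointwise.

``dP_CC = max - min`` of the averaged pulse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .exceptions import (
    BaselineTooShortError,
    DegeneratePulseError,
    EmptyBandError,
    NoCardiacPeakError,
    TooFewPulsesError,
)
from .io_formats import ICPFile

log = logging.getLogger(__name__)

MIN_SEGMENT_S = 10.0


@dataclass
class ICPSegment:
    """A contiguous stretch of the ICP trace."""

    values_mmHg: np.ndarray
    sampling_hz: float
    origin: str = "baseline"  # {baseline, infusion, plateau}

    def __post_init__(self) -> None:
        self.values_mmHg = np.asarray(self.values_mmHg, dtype=float)
        if not np.all(np.isfinite(self.values_mmHg)):
            raise ValueError("ICP segment must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.values_mmHg) / self.sampling_hz


@dataclass
class AveragePulse:
    """Ensemble-averaged single-cycle ICP waveform on a normalized cycle."""

    values_mmHg: np.ndarray
    period_s: float
    n_beats: int
    delta_p_cc_mmHg: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_p_cc_mmHg = float(np.max(self.values_mmHg) - np.min(self.values_mmHg))


def select_baseline(rec: ICPFile, window_s: float = 30.0, gap_s: float = 10.0) -> ICPSegment:
    """Baseline window of length ``window_s`` ending ``gap_s`` before infusion.

    Falls back to the full annotated baseline (with a warning) when it is
    shorter than requested; below 10 s the segment is unusable.
    """
    ann = rec.annotations
    end_s = min(ann.baseline_end_s, ann.infusion_start_s - gap_s)
    start_s = end_s - window_s
    if start_s < ann.baseline_start_s:
        available = ann.baseline_end_s - ann.baseline_start_s
        if available < MIN_SEGMENT_S:
            raise BaselineTooShortError(
                f"baseline is {available:.1f} s; at least {MIN_SEGMENT_S:.0f} s required"
            )
        log.warning(
            "baseline (%.1f s) shorter than requested window (%.1f s); using full baseline",
            available, window_s,
        )
        start_s, end_s = ann.baseline_start_s, ann.baseline_end_s
    i0 = int(round(start_s * rec.sampling_hz))
    i1 = int(round(end_s * rec.sampling_hz))
    return ICPSegment(rec.icp_mmHg[i0:i1], rec.sampling_hz, origin="baseline")


def estimate_cardiac_frequency(
    seg: ICPSegment, band: tuple[float, float] = (0.8, 2.5)
) -> float:
    """Frequency (Hz) of the largest spectral magnitude inside ``band``."""
    x = seg.values_mmHg
    if seg.duration_s < MIN_SEGMENT_S:
        raise BaselineTooShortError("need at least 10 s to estimate the cardiac frequency")
    x = x - np.mean(x)
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / seg.sampling_hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise EmptyBandError(f"no FFT bin inside cardiac band {band}")
    # amplitude of the best in-band tone; a flat/noise-only segment has none
    peak_amp = 2.0 * np.max(spectrum[in_band]) / len(x)
    if peak_amp < 1e-9 or peak_amp < 0.05 * np.std(x):
        raise NoCardiacPeakError("no spectral peak above noise floor in the cardiac band")
    return float(freqs[in_band][np.argmax(spectrum[in_band])])


def fft_bandpass(
    seg: ICPSegment,
    f_c: float,
    config: AnalysisConfig | None = None,
) -> ICPSegment:
    """FFT band filter around the cardiac fundamental and its harmonics.

    Keeps ``[band_low_factor * f_c, min(band_high_cap_hz, band_high_factor * f_c)]``
    (hard bin zeroing, or a raised-cosine transition of width ``taper_hz``)
    and, by default, the DC bin, then reconstructs by inverse FFT.
    """
    cfg = config or AnalysisConfig()
    lo = cfg.band_low_factor * f_c
    hi = min(cfg.band_high_cap_hz, cfg.band_high_factor * f_c)
    if hi <= lo:
        raise EmptyBandError(f"empty keep band [{lo:.3g}, {hi:.3g}] Hz")
    x = seg.values_mmHg
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / seg.sampling_hz)
    if cfg.taper_hz > 0:
        gain = _raised_cosine_gain(freqs, lo, hi, cfg.taper_hz)
    else:
        gain = ((freqs >= lo) & (freqs <= hi)).astype(float)
    gain[0] = 1.0 if cfg.keep_dc else 0.0
    filtered = np.fft.irfft(spectrum * gain, n=len(x))
    return ICPSegment(filtered, seg.sampling_hz, origin=seg.origin)


def _raised_cosine_gain(freqs: np.ndarray, lo: float, hi: float, width: float) -> np.ndarray:
    gain = np.zeros_like(freqs)
    core = (freqs >= lo) & (freqs <= hi)
    gain[core] = 1.0
    rising = (freqs > lo - width) & (freqs < lo)
    gain[rising] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[rising]) / width))
    falling = (freqs > hi) & (freqs < hi + width)
    gain[falling] = 0.5 * (1 + np.cos(np.pi * (freqs[falling] - hi) / width))
    return gain


def segment_pulses(
    seg: ICPSegment,
    f_c: float,
    config: AnalysisConfig | None = None,
) -> list[np.ndarray]:
    """Cut a filtered segment into single-beat pulses at detected peaks.

    Peaks need a minimum separation of 0.6 cardiac periods and a prominence of
    0.25 segment SDs (both configurable), which avoids double-counting the P2
    sub-peak in pulses where P2 exceeds P1.  Pulses are the half-open spans
    between consecutive peaks; beats whose length deviates more than 25% from
    the median beat length are discarded.
    """
    cfg = config or AnalysisConfig()
    x = seg.values_mmHg
    distance = max(1, int(round(cfg.peak_min_separation_cycles / f_c * seg.sampling_hz)))
    prominence = cfg.peak_prominence_sd * np.std(x)
    peaks, _ = find_peaks(x, distance=distance, prominence=max(prominence, 1e-12))
    pulses = [x[a:b] for a, b in zip(peaks[:-1], peaks[1:])]
    if len(pulses) < 3:
        raise TooFewPulsesError(f"only {len(pulses)} pulses segmented; at least 3 required")
    lengths = np.array([len(p) for p in pulses], dtype=float)
    median = float(np.median(lengths))
    keep = np.abs(lengths - median) <= cfg.beat_length_tolerance * median
    if np.sum(~keep):
        log.info("discarded %d of %d beats with outlying length", int(np.sum(~keep)), len(pulses))
    retained = [p for p, k in zip(pulses, keep) if k]
    if len(retained) < 3:
        raise TooFewPulsesError(f"only {len(retained)} pulses retained after length screening")
    return retained


def average_pulse(
    pulses: list[np.ndarray],
    sampling_hz: float,
    n_points: int = 32,
) -> AveragePulse:
    """Resample each pulse to ``n_points`` on a normalized cycle and average.

    Pulses are aligned at their starting peak (they begin at a detected peak
    by construction) and continued periodically for the resampling grid, so
    phase ``1`` maps back onto the starting peak of the next beat.
    """
    if len(pulses) < 3:
        raise TooFewPulsesError(f"need at least 3 pulses, got {len(pulses)}")
    grid = np.arange(n_points) / n_points
    resampled = np.empty((len(pulses), n_points))
    for i, p in enumerate(pulses):
        m = len(p)
        if m < 2:
            raise DegeneratePulseError("zero-length pulse cannot be resampled")
        phase = np.arange(m) / m
        resampled[i] = np.interp(grid, np.append(phase, 1.0), np.append(p, p[0]))
    mean_len = float(np.mean([len(p) for p in pulses]))
    return AveragePulse(
        values_mmHg=resampled.mean(axis=0),
        period_s=mean_len / sampling_hz,
        n_beats=len(pulses),
    )


def delta_p_cc(pulse: AveragePulse) -> float:
    """Peak-to-peak amplitude of the averaged pulse, in mmHg."""
    return pulse.delta_p_cc_mmHg


def extract_average_pulse(rec: ICPFile, config: AnalysisConfig | None = None) -> AveragePulse:
    """Full baseline chain: select, filter, segment, average."""
    cfg = config or AnalysisConfig()
    seg = select_baseline(rec, cfg.baseline_window_s, cfg.baseline_gap_s)
    f_c = estimate_cardiac_frequency(seg, cfg.cardiac_band_hz)
    filtered = fft_bandpass(seg, f_c, cfg)
    pulses = segment_pulses(filtered, f_c, cfg)
    return average_pulse(pulses, rec.sampling_hz, cfg.pulse_points)
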