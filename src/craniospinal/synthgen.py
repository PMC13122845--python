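"""Seeded synthetic cohort generator.

Patient recordings of this kind cannot be shared, so the pipeline is
exercised on synthetic cohorts whose per-subject ground truth is drawn from
truncated-normal distributions calibrated, by default, to the published
characteristics of a suspected-NPH cohort of 108 patients:

* heart rate during MRI 74 +/- 14 BPM, during the infusion test slightly
  lower and strongly rank-correlated (Gaussian copula, Spearman ~0.84);
* total cerebral arterial mean flow 426 +/- 102 mL/min, split over the two
  internal carotids and the basilar artery;
* baseline ICP pulse peak-to-peak amplitude 3.0 +/- 1.5 mmHg (the target
  dP_CC), riding on a baseline mean ICP near 11 mmHg together with a
  respiratory oscillation and white measurement noise;
* infusion response: first-order exponential approach to a plateau,
  amplitude 20 +/- 9 mmHg, time constant 210 +/- 60 s chosen so that
  plateau detection lands near the published 11-12 min infusion duration
  (and therefore near the published 17 mL infused volume at 1.5 mL/min).

Every random draw descends from one master seed through
``numpy.random.SeedSequence``; identical configuration and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import (
    FlowCurveFile,
    ICPFile,
    InfusionAnnotations,
    ManifestEntry,
    write_flow_curve,
    write_icp_recording,
    write_manifest,
)

N_FRAMES = 32


@dataclass(frozen=True)
class FieldDist:
    """Truncated normal distribution for one ground-truth field."""

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, rng: np.random.Generator, size=None):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                             size=size, random_state=rng)

    def from_normal(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws through the truncated-normal quantile
        function (Gaussian copula coupling)."""
        from scipy.stats import norm

        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.ppf(norm.cdf(z), a, b, loc=self.mean, scale=self.sd)


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    q_mean_ml_per_min: float
    vessel_shares: tuple[float, float, float]   # ICAL, ICAR, BA; sums to 1
    hr_mri_bpm: float
    hr_inf_bpm: float
    pulse_p2p_mmHg: float        # true cardiac peak-to-peak = target dP_CC
    icp_b_mmHg: float
    delta_p_inf_mmHg: float
    tau_s: float                 # plateau time constant
    resp_freq_hz: float
    resp_amp_mmHg: float
    noise_sd_mmHg: float
    seed: int

    def __post_init__(self) -> None:
        if abs(sum(self.vessel_shares) - 1.0) > 1e-9:
            raise ValueError("vessel shares must sum to 1")
        for name in ("q_mean_ml_per_min", "hr_mri_bpm", "hr_inf_bpm", "pulse_p2p_mmHg",
                     "icp_b_mmHg", "delta_p_inf_mmHg", "tau_s", "resp_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for hr in (self.hr_mri_bpm, self.hr_inf_bpm):
            if not 40 <= hr <= 150:
                raise ValueError("heart rates must lie in [40, 150] BPM")


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings (defaults: published-cohort calibration)."""

    n_subjects: int = 108
    seed: int = 0
    q_mean: FieldDist = field(default_factory=lambda: FieldDist(426.0, 102.0, 150.0, 900.0))
    hr_mri: FieldDist = field(default_factory=lambda: FieldDist(74.0, 14.0, 50.0, 120.0))
    hr_inf: FieldDist = field(default_factory=lambda: FieldDist(73.0, 13.0, 50.0, 120.0))
    hr_spearman: float = 0.84          # MRI vs infusion heart-rate rank coupling
    pulse_p2p: FieldDist = field(default_factory=lambda: FieldDist(3.0, 1.5, 0.5, 8.0))
    icp_b: FieldDist = field(default_factory=lambda: FieldDist(11.0, 4.0, 4.0, 30.0))
    delta_p_inf: FieldDist = field(default_factory=lambda: FieldDist(20.0, 9.0, 4.0, 60.0))
    tau: FieldDist = field(default_factory=lambda: FieldDist(210.0, 60.0, 60.0, 390.0))
    resp_freq: FieldDist = field(default_factory=lambda: FieldDist(0.25, 0.05, 0.10, 0.45))
    resp_amp: FieldDist = field(default_factory=lambda: FieldDist(1.5, 0.5, 0.0, 3.0))
    noise_sd: FieldDist = field(default_factory=lambda: FieldDist(0.20, 0.05, 0.05, 0.50))
    vessel_share_base: tuple[float, float, float] = (0.38, 0.38, 0.24)
    vessel_share_concentration: float = 60.0
    pulsatility: float = 0.8           # amplitude of the systolic bump in the flow waveform
    beat_jitter: float = 0.03          # beat-to-beat period jitter (fractional SD)
    sampling_hz: float = 100.0
    baseline_s: float = 300.0
    post_plateau_s: float = 300.0
    infusion_factor: float = 1.5       # infusion phase lasts factor * 4 * tau
    rate_ml_per_min: float = 1.5
    amplitude_tracks_pressure: bool = False  # optional: pulse amplitude grows with mean ICP


def draw_cohort_truth(config: GeneratorConfig) -> list[SubjectTruth]:
    """Draw the per-subject ground-truth table for a cohort."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_subjects
    # Gaussian-copula coupling of the two heart rates; the Pearson correlation
    # that yields a target Spearman rho_s on the copula is 2*sin(pi*rho_s/6).
    rho = 2.0 * np.sin(np.pi * config.hr_spearman / 6.0)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    hr_mri = config.hr_mri.from_normal(z1)
    hr_inf = config.hr_inf.from_normal(z2)
    shares = rng.dirichlet(
        np.asarray(config.vessel_share_base) * config.vessel_share_concentration, size=n
    )
    fields = {
        name: getattr(config, name).sample(rng, size=n)
        for name in ("q_mean", "pulse_p2p", "icp_b", "delta_p_inf", "tau",
                     "resp_freq", "resp_amp", "noise_sd")
    }
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n + 1)[1:]]
    truths = []
    for i in range(n):
        truths.append(SubjectTruth(
            subject_id=f"S{i + 1:03d}",
            q_mean_ml_per_min=float(fields["q_mean"][i]),
            vessel_shares=tuple(shares[i]),
            hr_mri_bpm=float(hr_mri[i]),
            hr_inf_bpm=float(hr_inf[i]),
            pulse_p2p_mmHg=float(fields["pulse_p2p"][i]),
            icp_b_mmHg=float(fields["icp_b"][i]),
            delta_p_inf_mmHg=float(fields["delta_p_inf"][i]),
            tau_s=float(fields["tau"][i]),
            resp_freq_hz=float(fields["resp_freq"][i]),
            resp_amp_mmHg=float(fields["resp_amp"][i]),
            noise_sd_mmHg=float(fields["noise_sd"][i]),
            seed=subject_seeds[i],
        ))
    return truths


def simulate_flow_curves(truth: SubjectTruth,
                         pulsatility: float | None = None) -> dict[str, FlowCurveFile]:
    """Three 32-frame arterial flow curves for one subject.

    Per vessel ``Q_v(t) = share_v * q_mean * w(t)`` with a waveform
    ``w(t) = 1 + a * (g(t) - mean(g))`` built from a Gaussian systolic bump
    centred at 0.15 T with width 0.08 T.  The 32-sample mean of each curve is
    the vessel's share of ``q_mean`` exactly.
    """
    a = pulsatility if pulsatility is not None else 0.8
    period = 60.0 / truth.hr_mri_bpm
    phase = np.arange(N_FRAMES) / N_FRAMES
    bump = np.exp(-0.5 * ((phase - 0.15) / 0.08) ** 2)
    w = 1.0 + a * (bump - np.mean(bump))
    if np.min(w) < 0:
        raise ValueError(f"pulsatility {a} drives the flow waveform negative")
    return {
        vessel: FlowCurveFile(vessel, period,
                              share * truth.q_mean_ml_per_min * w)
        for vessel, share in zip(("ICAL", "ICAR", "BA"), truth.vessel_shares)
    }


# ---------------------------------------------------------------------------
# ICP pulse template
# ---------------------------------------------------------------------------

def _pulse_template(n: int = 4096) -> np.ndarray:
    """One-cycle ICP pulse template, peak-to-peak normalized to 1.

    Smooth periodic waveform with the three classical sub-peaks (percussion
    P1, tidal P2, dicrotic P3; P2/P1 = 1.1) built from circularly wrapped
    Gaussian bumps, plus a shallow negative bump that gives the end-diastolic
    minimum a defined, rounded shape.  Smoothness keeps essentially all
    energy below the 10th harmonic, so the analysis band filter leaves the
    shape intact.
    """
    phase = np.arange(n) / n
    bumps = (
        (1.00, 0.12, 0.055),   # P1
        (1.10, 0.30, 0.075),   # P2
        (0.75, 0.52, 0.080),   # P3
        (-0.30, 0.85, 0.110),  # end-diastolic trough
    )
    y = np.zeros(n)
    for amp, center, width in bumps:
        for wrap in (-1.0, 0.0, 1.0):
            y += amp * np.exp(-0.5 * ((phase - center - wrap) / width) ** 2)
    return (y - np.min(y)) / np.ptp(y)


_TEMPLATE = _pulse_template()


def simulate_icp(truth: SubjectTruth, config: GeneratorConfig | None = None) -> ICPFile:
    """Synthetic lumbar ICP recording: baseline, infusion rise, plateau.

    ``s(t) = trend(t) + pulse(t) + resp(t) + noise`` with a first-order
    exponential trend after infusion start, a cardiac pulse train built from
    the sub-peaked template with beat-to-beat period jitter, a sinusoidal
    respiratory oscillation and white noise.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(truth.seed)
    fs = cfg.sampling_hz
    infusion_s = cfg.infusion_factor * 4.0 * truth.tau_s
    total_s = cfg.baseline_s + infusion_s + cfg.post_plateau_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    trend = np.full(n, truth.icp_b_mmHg)
    after = t >= cfg.baseline_s
    trend[after] += truth.delta_p_inf_mmHg * (
        1.0 - np.exp(-(t[after] - cfg.baseline_s) / truth.tau_s)
    )

    mean_period = 60.0 / truth.hr_inf_bpm
    n_beats = int(np.ceil(total_s / mean_period)) + 2
    periods = mean_period * (1.0 + cfg.beat_jitter * rng.standard_normal(n_beats))
    periods = np.maximum(periods, 0.3 * mean_period)
    starts = np.concatenate([[0.0], np.cumsum(periods)]) - rng.uniform(0, mean_period)
    idx = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[idx]) / periods[np.minimum(idx, n_beats - 1)]
    template_x = np.arange(len(_TEMPLATE)) / len(_TEMPLATE)
    pulse_shape = np.interp(np.mod(phase, 1.0), template_x, _TEMPLATE, period=1.0)
    amplitude = truth.pulse_p2p_mmHg
    if cfg.amplitude_tracks_pressure:
        amplitude = amplitude * trend / truth.icp_b_mmHg
    pulse = amplitude * pulse_shape

    resp = truth.resp_amp_mmHg * np.sin(2.0 * np.pi * truth.resp_freq_hz * t)
    noise = truth.noise_sd_mmHg * rng.standard_normal(n)

    ann = InfusionAnnotations(
        baseline_start_s=0.0,
        baseline_end_s=cfg.baseline_s,
        infusion_start_s=cfg.baseline_s,
        infusion_rate_ml_per_min=cfg.rate_ml_per_min,
        recording_end_s=n / fs,
    )
    return ICPFile(trend + pulse + resp + noise, fs, ann)


def truth_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    rows = []
    for tr in truths:
        row = {k: v for k, v in tr.__dict__.items() if k != "vessel_shares"}
        row["share_ical"], row["share_icar"], row["share_ba"] = tr.vessel_shares
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic cohort (flow CSVs, ICP CSV + YAML sidecar,
    manifest, ground-truth table); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = draw_cohort_truth(config)
    entries = []
    for tr in truths:
        sdir = out / tr.subject_id
        sdir.mkdir(exist_ok=True)
        flow_paths = {}
        for vessel, f in simulate_flow_curves(tr, config.pulsatility).items():
            p = sdir / f"flow_{vessel.lower()}.csv"
            write_flow_curve(f, p)
            flow_paths[vessel] = p.relative_to(out)
        rec = simulate_icp(tr, config)
        icp_path = sdir / "icp.csv"
        ann_path = sdir / "icp_annotations.yaml"
        write_icp_recording(rec, icp_path, ann_path)
        entries.append(ManifestEntry(
            tr.subject_id, flow_paths,
            icp_path.relative_to(out), ann_path.relative_to(out),
        ))
    manifest = out / "manifest.csv"
    write_manifest(entries, manifest)
    truth_table(truths).to_csv(out / "truth.csv", index=False, float_format="%.12g")
    return manifest


def paper_calibration(n_subjects: int = 108, seed: int = 0) -> GeneratorConfig:
    """Default published-cohort calibration (the class defaults)."""
    return GeneratorConfig(n_subjects=n_subjects, seed=seed)


def scaled(config: GeneratorConfig, **overrides) -> GeneratorConfig:
    """Copy a configuration with selected fields replaced."""
    return replace(config, **overrides)
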