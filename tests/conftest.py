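import dataclasses

import numpy as np
import pytest

from craniospinal import AnalysisConfig, GeneratorConfig, SubjectTruth
from craniospinal.flow_volume import FlowCurve
from craniospinal.io_formats import ICPFile, InfusionAnnotations


@pytest.fixture
def config():
    return AnalysisConfig()


def make_flow(values_ml_per_min, period_s):
    """FlowCurve from mL/min samples (the unit clinical exports use)."""
    return FlowCurve(np.asarray(values_ml_per_min, dtype=float) / 60.0, period_s)


def make_icp(values, fs=100.0, baseline_end=None, infusion_start=None, rate=1.5):
    """ICPFile around a raw sample vector with simple annotations."""
    n = len(values)
    end = n / fs
    infusion_start = end if infusion_start is None else infusion_start
    baseline_end = infusion_start if baseline_end is None else baseline_end
    ann = InfusionAnnotations(0.0, baseline_end, infusion_start, rate, end)
    return ICPFile(np.asarray(values, dtype=float), fs, ann)


def make_truth(**overrides):
    """A mid-cohort synthetic subject; override individual fields as needed."""
    base = dict(
        subject_id="S001",
        q_mean_ml_per_min=426.0,
        vessel_shares=(0.38, 0.38, 0.24),
        hr_mri_bpm=74.0,
        hr_inf_bpm=72.0,
        pulse_p2p_mmHg=3.0,
        icp_b_mmHg=11.0,
        delta_p_inf_mmHg=20.0,
        tau_s=210.0,
        resp_freq_hz=0.25,
        resp_amp_mmHg=1.5,
        noise_sd_mmHg=0.2,
        seed=42,
    )
    base.update(overrides)
    return SubjectTruth(**base)


def short_gen(**overrides):
    """Generator settings producing a short recording (baseline-dominated),
    for tests that only exercise the baseline pulse chain."""
    defaults = dict(baseline_s=45.0, post_plateau_s=0.0)
    defaults.update(overrides)
    return dataclasses.replace(GeneratorConfig(), **defaults)


@pytest.fixture(scope="session")
def default_cohort_table():
    """One analyzed default-calibration cohort (n=108, seed=11), shared
    across tests that only read it."""
    from craniospinal import analyze_cohort_in_memory, draw_cohort_truth

    gen = GeneratorConfig(n_subjects=108, seed=11)
    truths = draw_cohort_truth(gen)
    return analyze_cohort_in_memory(truths, gen), truths
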