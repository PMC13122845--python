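"""Subject- and cohort-level orchestration of the full analysis chain."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import pandas as pd

from .cohort import c_physio
from .config import AnalysisConfig
from .exceptions import CraniospinalError
from .flow_volume import FlowCurve, delta_v_art, sum_arterial_flows, volume_curve
from .icp_pulse import extract_average_pulse
from .infusion import analyze_infusion
from .io_formats import (
    FlowCurveFile,
    ICPFile,
    ManifestEntry,
    read_flow_curves,
    read_icp_recording,
)

log = logging.getLogger(__name__)


@dataclass
class SubjectMetrics:
    subject_id: str
    hr_mri_bpm: float
    cardiac_period_s: float
    mean_arterial_flow_ml_per_min: float
    delta_v_art_ml: float
    delta_p_cc_mmHg: float
    c_physio_ml_per_mmHg: float
    hr_inf_bpm: float
    icp_b_mmHg: float
    icp_p_mmHg: float
    delta_p_inf_mmHg: float
    delta_t_inf_s: float
    delta_v_inf_ml: float
    c_inf_ml_per_mmHg: float
    rout_mmHg_per_ml_per_min: float
    group: str = ""


def analyze_subject(
    subject_id: str,
    flows: dict[str, FlowCurveFile],
    icp: ICPFile,
    config: AnalysisConfig | None = None,
    group: str = "",
) -> SubjectMetrics:
    """Run the arterial, pulse and infusion chains for one subject."""
    cfg = config or AnalysisConfig()

    curves: dict[str, FlowCurve] = {v: f.to_curve() for v, f in flows.items()}
    q_art = sum_arterial_flows(curves["ICAL"], curves["ICAR"], curves["BA"],
                               clamp_negative=cfg.clamp_negative_flow)
    v_art = volume_curve(q_art, subtract_mean=cfg.subtract_mean_flow)
    dv_art = delta_v_art(v_art)

    pulse = extract_average_pulse(icp, cfg)
    inf = analyze_infusion(icp, cfg)

    return SubjectMetrics(
        subject_id=subject_id,
        hr_mri_bpm=60.0 / q_art.period_s,
        cardiac_period_s=q_art.period_s,
        mean_arterial_flow_ml_per_min=q_art.mean_flow_ml_per_min,
        delta_v_art_ml=dv_art,
        delta_p_cc_mmHg=pulse.delta_p_cc_mmHg,
        c_physio_ml_per_mmHg=c_physio(dv_art, pulse.delta_p_cc_mmHg),
        hr_inf_bpm=60.0 / pulse.period_s,
        icp_b_mmHg=inf.icp_b_mmHg,
        icp_p_mmHg=inf.icp_p_mmHg,
        delta_p_inf_mmHg=inf.delta_p_inf_mmHg,
        delta_t_inf_s=inf.delta_t_inf_s,
        delta_v_inf_ml=inf.delta_v_inf_ml,
        c_inf_ml_per_mmHg=inf.c_inf_ml_per_mmHg,
        rout_mmHg_per_ml_per_min=inf.rout_mmHg_per_ml_per_min,
        group=group,
    )


def analyze_manifest(entries: list[ManifestEntry],
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyze every manifest subject; failures are logged, never silently dropped."""
    rows, failures = [], []
    for e in entries:
        try:
            flows = read_flow_curves(e.flow_paths)
            icp = read_icp_recording(e.icp_path, e.annotation_path)
            rows.append(asdict(analyze_subject(e.subject_id, flows, icp, config, e.group)))
        except CraniospinalError as exc:
            log.error("subject %s excluded: %s", e.subject_id, exc)
            failures.append((e.subject_id, str(exc)))
    if failures:
        log.warning("excluded %d of %d subjects", len(failures), len(entries))
    return pd.DataFrame(rows)


def analyze_cohort_in_memory(truths, gen_config=None,
                             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyze simulated subjects without touching disk (same chain as the CLI)."""
    from .synthgen import GeneratorConfig, simulate_flow_curves, simulate_icp

    gen = gen_config or GeneratorConfig()
    rows = []
    for tr in truths:
        flows = simulate_flow_curves(tr, gen.pulsatility)
        icp = simulate_icp(tr, gen)
        rows.append(asdict(analyze_subject(tr.subject_id, flows, icp, config)))
    return pd.DataFrame(rows)
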