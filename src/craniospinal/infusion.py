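"""Infusion-phase analysis: plateau detection and infusion-derived compliance.

A constant-rate lumbar infusion raises mean ICP from the baseline level to a
steady-state plateau.  The infusion-derived quantities are

    dP_INF = mean plateau ICP - mean baseline ICP        (mmHg)
    dV_INF = rate * dt_INF                               (mL, rate in mL/min)
    C_INF  = dV_INF / dP_INF                             (mL/mmHg)
    Rout   = dP_INF / rate                               (mmHg/mL/min)

where ``dt_INF`` is the time from infusion start to plateau onset.  Plateau
onset is found on the slow trend (10-s moving average, which cancels cardiac
and respiratory oscillations) as the earliest analysis window whose
regression slope is below ``slope_max`` and whose mean has essentially
reached the highest level seen later in the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .exceptions import NonPositivePressureChangeError, NoPlateauError
from .io_formats import ICPFile


@dataclass
class Plateau:
    start_s: float
    end_s: float
    delta_t_inf_s: float


@dataclass
class InfusionMetrics:
    icp_b_mmHg: float
    icp_p_mmHg: float
    delta_p_inf_mmHg: float
    delta_t_inf_s: float
    delta_v_inf_ml: float
    c_inf_ml_per_mmHg: float
    rout_mmHg_per_ml_per_min: float


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation, O(n) via cumulative sums."""
    if width <= 1:
        return x.astype(float)
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    idx = np.arange(n)
    left = np.maximum(idx - width // 2, 0)
    right = np.minimum(idx + (width - width // 2), n)
    return (cs[right] - cs[left]) / (right - left)


def detect_plateau(rec: ICPFile, config: AnalysisConfig | None = None) -> Plateau:
    """Locate the plateau onset after infusion start.

    Consecutive windows of ``plateau_window_s`` (stride defaults to the window
    length) are evaluated on the moving-average trend.  A window qualifies
    when its least-squares slope is at most ``plateau_slope_max_mmhg_per_min``
    and its mean lies within ``plateau_level_tol_mmhg`` of the largest
    windowed mean from that point on (so a transient pause on the rising limb
    is not mistaken for the plateau).  The plateau spans from the first
    qualifying window's start to the end of the recording.
    """
    cfg = config or AnalysisConfig()
    fs = rec.sampling_hz
    ann = rec.annotations
    trend = _moving_average(rec.icp_mmHg, int(round(cfg.trend_window_s * fs)))

    i_inf = int(round(ann.infusion_start_s * fs))
    i_end = int(round(ann.recording_end_s * fs))
    w = int(round(cfg.plateau_window_s * fs))
    stride = int(round((cfg.plateau_stride_s or cfg.plateau_window_s) * fs))
    if i_end - i_inf < 2 * w:
        raise NoPlateauError("need at least two analysis windows after infusion start")

    starts = np.arange(i_inf, i_end - w + 1, stride)
    t_rel = (np.arange(w) - (w - 1) / 2.0) / fs
    denom = float(np.sum(t_rel * t_rel))
    means = np.empty(len(starts))
    slopes = np.empty(len(starts))
    for k, s in enumerate(starts):
        y = trend[s:s + w]
        means[k] = np.mean(y)
        slopes[k] = np.dot(t_rel, y - means[k]) / denom  # mmHg/s
    later_max = np.maximum.accumulate(means[::-1])[::-1]

    slope_max = cfg.plateau_slope_max_mmhg_per_min / 60.0
    ok = (slopes <= slope_max) & (means >= later_max - cfg.plateau_level_tol_mmhg)
    hits = np.flatnonzero(ok)
    if len(hits) == 0:
        raise NoPlateauError("no window satisfies the plateau criteria (slope/level)")
    start_s = starts[hits[0]] / fs
    return Plateau(start_s=start_s, end_s=ann.recording_end_s,
                   delta_t_inf_s=start_s - ann.infusion_start_s)


def infusion_metrics(rec: ICPFile, plateau: Plateau,
                     config: AnalysisConfig | None = None) -> InfusionMetrics:
    """Populate all infusion-derived quantities from the raw trace.

    Baseline and plateau means are taken on the *raw* signal (the annotated
    baseline window and the detected plateau interval): mean ICP must include
    the slow components the pulse filter would remove.
    """
    fs = rec.sampling_hz
    ann = rec.annotations
    b0, b1 = int(round(ann.baseline_start_s * fs)), int(round(ann.baseline_end_s * fs))
    p0, p1 = int(round(plateau.start_s * fs)), int(round(plateau.end_s * fs))
    if b1 <= b0:
        raise NonPositivePressureChangeError("annotated baseline window is empty")
    icp_b = float(np.mean(rec.icp_mmHg[b0:b1]))
    icp_p = float(np.mean(rec.icp_mmHg[p0:p1]))
    delta_p = icp_p - icp_b
    if delta_p <= 0:
        raise NonPositivePressureChangeError(
            f"plateau ICP ({icp_p:.2f}) does not exceed baseline ICP ({icp_b:.2f})"
        )
    rate = ann.infusion_rate_ml_per_min
    delta_t_min = plateau.delta_t_inf_s / 60.0
    delta_v = rate * delta_t_min
    return InfusionMetrics(
        icp_b_mmHg=icp_b,
        icp_p_mmHg=icp_p,
        delta_p_inf_mmHg=delta_p,
        delta_t_inf_s=plateau.delta_t_inf_s,
        delta_v_inf_ml=delta_v,
        c_inf_ml_per_mmHg=delta_v / delta_p,
        rout_mmHg_per_ml_per_min=delta_p / rate,
    )


def analyze_infusion(rec: ICPFile, config: AnalysisConfig | None = None) -> InfusionMetrics:
    """Plateau detection followed by metric computation."""
    return infusion_metrics(rec, detect_plateau(rec, config), config)
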