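"""Total arterial inflow and the cerebral arterial volume-change curve.

The arterial side of the physiological compliance estimate works on
cardiac-gated flow curves (32 frames per reconstructed cycle) from the two
internal carotid arteries and the basilar artery:

1. the three vessel curves are summed pointwise into the total cerebral
   arterial inflow ``Q_ART``;
2. ``Q_ART`` is integrated over the cycle (cumulative trapezoid, closing the
   cycle periodically) into the volume-change curve ``V_ART``;
3. the amplitude ``dV_ART = max(V_ART) - min(V_ART)`` is the arterial volume
   change per heart beat, in mL.

By default the mean flow is *not* subtracted before integration, so with
strictly positive inflow the amplitude equals the full-cycle integral
``mean(Q) * T``.  The alternative convention (subtracting the mean first,
which isolates the pulsatile volume excursion) is available through
``subtract_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import PeriodMismatchError

N_FRAMES = 32


@dataclass
class FlowCurve:
    """One cycle of flow, uniformly sampled at ``t = i * T / n`` (half-open cycle).

    Parameters
    ----------
    values_ml_per_s : ndarray, shape (32,)
        Flow samples in mL/s.
    period_s : float
        Cardiac period in seconds.
    """

    values_ml_per_s: np.ndarray
    period_s: float

    def __post_init__(self) -> None:
        self.values_ml_per_s = np.asarray(self.values_ml_per_s, dtype=float)
        if self.values_ml_per_s.ndim != 1:
            raise ValueError("flow values must be one-dimensional")
        if not np.all(np.isfinite(self.values_ml_per_s)):
            raise ValueError("flow values must be finite")
        if not (np.isfinite(self.period_s) and self.period_s > 0):
            raise ValueError("period_s must be finite and positive")

    @property
    def mean_flow_ml_per_min(self) -> float:
        return float(np.mean(self.values_ml_per_s) * 60.0)


@dataclass
class VolumeCurve:
    """Cumulative integral of a flow curve over one cycle.

    ``values_ml[i]`` is the volume accumulated up to ``t = i * T / n``
    (``values_ml[0] == 0``); the periodic closing point at ``t = T`` is kept
    separately so that the amplitude sees the whole cycle.
    """

    values_ml: np.ndarray
    closing_value_ml: float
    period_s: float
    subtract_mean: bool = False
    delta_v_art_ml: float = field(init=False)

    def __post_init__(self) -> None:
        closed = np.append(self.values_ml, self.closing_value_ml)
        self.delta_v_art_ml = float(np.max(closed) - np.min(closed))


def sum_arterial_flows(
    ical: FlowCurve,
    icar: FlowCurve,
    ba: FlowCurve,
    clamp_negative: bool = False,
) -> FlowCurve:
    """Pointwise sum of the three arterial inflow curves.

    With ``clamp_negative`` each vessel's negative samples are zeroed before
    summation, mimicking flow software that extracts inflow as positive
    values only.
    """
    curves = (ical, icar, ba)
    n = len(ical.values_ml_per_s)
    if any(len(c.values_ml_per_s) != n for c in curves):
        raise ValueError("flow curves must have identical length")
    periods = [c.period_s for c in curves]
    if max(periods) - min(periods) > 1e-9 * max(periods):
        raise PeriodMismatchError(f"cardiac periods differ across vessels: {periods}")
    values = [np.maximum(c.values_ml_per_s, 0.0) if clamp_negative else c.values_ml_per_s
              for c in curves]
    return FlowCurve(values[0] + values[1] + values[2], ical.period_s)


def volume_curve(q: FlowCurve, subtract_mean: bool = False) -> VolumeCurve:
    """Integrate a flow curve into the volume-change curve.

    Cumulative trapezoidal quadrature with ``dt = T / n``; the cycle is closed
    periodically by re-using the first sample at ``t = T``, which makes the
    full-cycle integral exactly ``mean(q) * T``.
    """
    y = q.values_ml_per_s.astype(float)
    if subtract_mean:
        y = y - np.mean(y)
    n = len(y)
    dt = q.period_s / n
    nodes = np.append(y, y[0])                   # periodic closure at t = T
    increments = 0.5 * dt * (nodes[:-1] + nodes[1:])
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    return VolumeCurve(
        values_ml=cumulative[:n],
        closing_value_ml=float(cumulative[n]),
        period_s=q.period_s,
        subtract_mean=subtract_mean,
    )


def delta_v_art(v: VolumeCurve) -> float:
    """Amplitude (max - min) of the volume curve, in mL."""
    return v.delta_v_art_ml
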