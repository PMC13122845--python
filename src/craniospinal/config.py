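"""Analysis configuration.

All thresholds of the processing chain live in one flat dataclass so that a
run can be reproduced from the logged configuration alone.  Values are chosen
for a lumbar ICP recording sampled at ~100 Hz and 32-frame cardiac-gated flow
curves; every one of them can be overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    # --- arterial volume ---
    subtract_mean_flow: bool = False    # subtract mean flow before integrating
    clamp_negative_flow: bool = False   # zero negative flow samples per vessel

    # --- baseline ICP pulse ---
    baseline_window_s: float = 30.0     # analysed baseline length
    baseline_gap_s: float = 10.0        # guard gap before infusion start
    cardiac_band_hz: tuple[float, float] = (0.8, 2.5)   # 48-150 BPM
    band_low_factor: float = 0.66       # low cutoff = factor * cardiac frequency
    band_high_factor: float = 10.0      # high cutoff = factor * cardiac frequency ...
    band_high_cap_hz: float = 15.0      # ... capped here
    keep_dc: bool = True                # retain the mean in the filtered signal
    taper_hz: float = 0.0               # >0: raised-cosine transition instead of hard edges
    peak_min_separation_cycles: float = 0.6   # min peak spacing, in cardiac periods
    peak_prominence_sd: float = 0.25          # prominence threshold, in segment SDs
    beat_length_tolerance: float = 0.25       # reject beats deviating more from median length
    pulse_points: int = 32                    # resampled points per averaged cycle

    # --- infusion plateau ---
    plateau_window_s: float = 60.0
    plateau_stride_s: float | None = None     # None -> non-overlapping windows
    plateau_slope_max_mmhg_per_min: float = 0.2
    plateau_level_tol_mmhg: float = 1.0
    trend_window_s: float = 10.0              # moving average removing cardiac/respiratory content

    # --- statistics ---
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_window_s < 10:
            raise ValueError("baseline_window_s must be at least 10 s")
        lo, hi = self.cardiac_band_hz
        if not 0 < lo < hi:
            raise ValueError("cardiac_band_hz must satisfy 0 < low < high")
        if self.pulse_points < 4:
            raise ValueError("pulse_points must be at least 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cardiac_band_hz" in data:
            data["cardiac_band_hz"] = tuple(data["cardiac_band_hz"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cardiac_band_hz"] = list(data["cardiac_band_hz"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def log_effective(self) -> None:
        log.info("effective configuration: %s", dataclasses.asdict(self))
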