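"""On-disk formats: flow curves, ICP recordings, annotations, manifests, reports.

One declared dialect: comma-delimited UTF-8 with a single header line; the
infusion annotations and sampling rate live in a YAML sidecar next to the ICP
trace.  Flow is stored in mL/min (as clinical software emits it) and converted
to mL/s exactly once, at load.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    AnnotationError,
    EmptyTraceError,
    FrameCountError,
    ManifestError,
    MissingVesselError,
    NonUniformSamplingError,
    PeriodMismatchError,
)

log = logging.getLogger(__name__)

VESSELS = ("ICAL", "ICAR", "BA")
N_FRAMES = 32


# ---------------------------------------------------------------------------
# flow curves
# ---------------------------------------------------------------------------

@dataclass
class FlowCurveFile:
    """One vessel's flow curve as stored on disk (mL/min, 32 frames)."""

    vessel_id: str
    cardiac_period_s: float
    flow_ml_per_min: np.ndarray

    def __post_init__(self) -> None:
        if self.vessel_id not in VESSELS:
            raise MissingVesselError(f"unknown vessel_id {self.vessel_id!r}; expected one of {VESSELS}")
        self.flow_ml_per_min = np.asarray(self.flow_ml_per_min, dtype=float)
        if len(self.flow_ml_per_min) != N_FRAMES:
            raise FrameCountError(
                f"vessel {self.vessel_id}: {len(self.flow_ml_per_min)} frames, expected {N_FRAMES}"
            )
        if not np.all(np.isfinite(self.flow_ml_per_min)):
            raise ValueError(f"vessel {self.vessel_id}: non-finite flow values")
        if not (np.isfinite(self.cardiac_period_s) and self.cardiac_period_s > 0):
            raise ValueError("cardiac_period_s must be finite and positive")

    def to_curve(self):
        """Convert to the internal mL/s representation."""
        from .flow_volume import FlowCurve

        return FlowCurve(self.flow_ml_per_min / 60.0, self.cardiac_period_s)


def write_flow_curve(f: FlowCurveFile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "vessel_id": f.vessel_id,
            "cardiac_period_s": f.cardiac_period_s,
            "frame": np.arange(len(f.flow_ml_per_min)),
            "flow_ml_per_min": f.flow_ml_per_min,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_flow_curve(path: str | Path) -> FlowCurveFile:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise EmptyTraceError(f"{path}: cannot parse ({exc})") from exc
    required = {"vessel_id", "cardiac_period_s", "frame", "flow_ml_per_min"}
    if not required.issubset(df.columns):
        raise MissingVesselError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if not np.issubdtype(df["flow_ml_per_min"].dtype, np.number):
        raise EmptyTraceError(f"{path}: non-numeric flow values")
    vessels = df["vessel_id"].unique()
    if len(vessels) != 1:
        raise MissingVesselError(f"{path}: expected a single vessel per file, found {list(vessels)}")
    periods = df["cardiac_period_s"].unique()
    if len(periods) != 1:
        raise PeriodMismatchError(f"{path}: inconsistent cardiac_period_s within file")
    frames = df.sort_values("frame")
    if len(frames) != N_FRAMES:
        raise FrameCountError(f"{path}: {len(frames)} frames, expected {N_FRAMES}")
    return FlowCurveFile(str(vessels[0]), float(periods[0]), frames["flow_ml_per_min"].to_numpy())


def read_flow_curves(paths: dict[str, str | Path] | list[str | Path]) -> dict[str, FlowCurveFile]:
    """Read the three vessel files; returns curves keyed by vessel id.

    Accepts either a vessel->path mapping or a list of three paths whose
    headers declare the vessel.
    """
    files = [read_flow_curve(p) for p in (paths.values() if isinstance(paths, dict) else paths)]
    by_vessel = {f.vessel_id: f for f in files}
    missing = set(VESSELS) - set(by_vessel)
    if missing:
        raise MissingVesselError(f"missing vessel(s): {sorted(missing)}")
    periods = {v: by_vessel[v].cardiac_period_s for v in VESSELS}
    pmin, pmax = min(periods.values()), max(periods.values())
    if pmax - pmin > 1e-9 * pmax:
        raise PeriodMismatchError(f"cardiac periods differ across vessels: {periods}")
    return by_vessel


# ---------------------------------------------------------------------------
# ICP recording + annotations
# ---------------------------------------------------------------------------

@dataclass
class InfusionAnnotations:
    baseline_start_s: float
    baseline_end_s: float
    infusion_start_s: float
    infusion_rate_ml_per_min: float
    recording_end_s: float

    def __post_init__(self) -> None:
        if not self.baseline_start_s <= self.baseline_end_s <= self.infusion_start_s:
            raise AnnotationError(
                "annotations must satisfy baseline_start <= baseline_end <= infusion_start"
            )
        if self.infusion_rate_ml_per_min <= 0:
            raise AnnotationError("infusion_rate_ml_per_min must be positive")
        if self.recording_end_s <= self.infusion_start_s:
            raise AnnotationError("recording must extend beyond infusion start")


@dataclass
class ICPFile:
    """Uniformly sampled lumbar ICP trace with infusion annotations."""

    icp_mmHg: np.ndarray
    sampling_hz: float
    annotations: InfusionAnnotations

    def __post_init__(self) -> None:
        self.icp_mmHg = np.asarray(self.icp_mmHg, dtype=float)
        if len(self.icp_mmHg) == 0:
            raise EmptyTraceError("empty ICP trace")
        if not np.all(np.isfinite(self.icp_mmHg)):
            raise ValueError("ICP trace must be finite")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        span = len(self.icp_mmHg) / self.sampling_hz
        if self.annotations.recording_end_s > span + 1.0 / self.sampling_hz:
            raise AnnotationError(
                f"annotations extend to {self.annotations.recording_end_s:.1f} s "
                f"but the trace spans {span:.1f} s"
            )

    @property
    def duration_s(self) -> float:
        return len(self.icp_mmHg) / self.sampling_hz

    def time_s(self) -> np.ndarray:
        return np.arange(len(self.icp_mmHg)) / self.sampling_hz


def write_icp_recording(rec: ICPFile, path: str | Path, annotation_path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.time_s(), "icp_mmHg": rec.icp_mmHg})
    df.to_csv(path, index=False, float_format="%.8g")
    sidecar = {"sampling_hz": float(rec.sampling_hz), **asdict(rec.annotations)}
    Path(annotation_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_icp_recording(path: str | Path, annotation_path: str | Path) -> ICPFile:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise EmptyTraceError(f"{path}: empty ICP trace")
    if not {"time_s", "icp_mmHg"}.issubset(df.columns):
        raise EmptyTraceError(f"{path}: expected columns time_s, icp_mmHg")
    meta = yaml.safe_load(Path(annotation_path).read_text())
    try:
        fs = float(meta.pop("sampling_hz"))
        ann = InfusionAnnotations(**meta)
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"{annotation_path}: missing or invalid annotation fields ({exc})") from exc
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if np.max(np.abs(dt - 1.0 / fs)) > 0.01 / fs:
            raise NonUniformSamplingError(f"{path}: timestamps deviate from uniform {fs} Hz sampling")
    return ICPFile(df["icp_mmHg"].to_numpy(), fs, ann)


# ---------------------------------------------------------------------------
# cohort manifest and subject report
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "flow_ical", "flow_icar", "flow_ba", "icp", "annotations", "group"]


@dataclass
class ManifestEntry:
    subject_id: str
    flow_paths: dict[str, Path]
    icp_path: Path
    annotation_path: Path
    group: str = ""


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    rows = [
        {
            "subject_id": e.subject_id,
            "flow_ical": str(e.flow_paths["ICAL"]),
            "flow_icar": str(e.flow_paths["ICAR"]),
            "flow_ba": str(e.flow_paths["BA"]),
            "icp": str(e.icp_path),
            "annotations": str(e.annotation_path),
            "group": e.group,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    df = pd.read_csv(path, dtype=str).fillna("")
    if not set(MANIFEST_COLUMNS[:-1]).issubset(df.columns):
        raise ManifestError(f"{path}: manifest needs columns {MANIFEST_COLUMNS[:-1]}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"{path}: duplicate subject_id(s) {dupes}")
    base = Path(path).parent
    entries = []
    for row in df.itertuples(index=False):
        paths = {
            "ICAL": base / row.flow_ical,
            "ICAR": base / row.flow_icar,
            "BA": base / row.flow_ba,
        }
        icp, ann = base / row.icp, base / row.annotations
        missing = [str(p) for p in [*paths.values(), icp, ann] if not p.exists()]
        if missing:
            raise ManifestError(f"subject {row.subject_id}: missing file(s) {missing}")
        entries.append(
            ManifestEntry(row.subject_id, paths, icp, ann, getattr(row, "group", "") or "")
        )
    return entries


REPORT_COLUMNS = [
    "subject_id", "group",
    "hr_mri_bpm", "cardiac_period_s", "mean_arterial_flow_ml_per_min",
    "delta_v_art_ml", "delta_p_cc_mmHg", "c_physio_ml_per_mmHg",
    "hr_inf_bpm", "icp_b_mmHg", "icp_p_mmHg",
    "delta_p_inf_mmHg", "delta_t_inf_s", "delta_v_inf_ml",
    "c_inf_ml_per_mmHg", "rout_mmHg_per_ml_per_min",
]


def write_subject_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-subject metrics table with a stable column order."""
    cols = [c for c in REPORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, index=False, float_format="%.12g")


def read_subject_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
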