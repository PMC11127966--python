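"""On-disk formats: recordings, step tables, feature matrices, configs, reports.

Everything is plain text for inspectability: recordings are CSV
(``t, ax, ay, az, gx, gy, gz``, SI units) with a JSON sidecar for metadata;
step tables and feature matrices are CSV; configs are YAML with strict
(unknown-key-rejecting) parsing; reports are JSON plus a Markdown table.
Lengths are in cm externally, signals in SI units throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import SIGNAL_COLUMNS, FormatError, ImuRecording, StepTable

#: a timestamp gap larger than this many sample periods is a format error
MAX_GAP_PERIODS = 1.5


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, loadable from YAML."""

    sampling_rate: float = 128.0
    filter_cutoff: float = 20.0
    n_folds: int = 5
    averaging_levels: tuple = (1, 3, 5, 10)
    window_lengths: tuple = (1.0, 5.0)
    model_family: str = "gbt"
    max_features: int = 34
    selection_model_family: str = "lr"
    pendulum_length_m: float = 0.88  # population constant: no per-subject calibration
    seed: int = 0
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.filter_cutoff >= self.sampling_rate / 2.0:
            raise ValueError("filter_cutoff must be below the Nyquist frequency")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(int(n) != n or n < 1 for n in self.averaging_levels):
            raise ValueError("averaging_levels must be positive integers")
        self.averaging_levels = tuple(int(n) for n in self.averaging_levels)
        self.window_lengths = tuple(float(w) for w in self.window_lengths)


def read_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are errors, not warnings."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["averaging_levels"] = list(cfg.averaging_levels)
    data["window_lengths"] = list(cfg.window_lengths)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rec.to_frame().to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "condition": rec.condition,
        "bout_id": rec.bout_id,
        "sampling_rate": rec.sampling_rate,
        "axes": {"x": "mediolateral", "y": "vertical", "z": "anterior-posterior"},
        "units": {"acc": "m/s^2", "gyro": "deg/s", "t": "s"},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(path: str | Path) -> ImuRecording:
    """Read a recording CSV (+ optional sidecar); validates schema/uniformity."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing signal columns {missing}")

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    t = df["t"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        fs = meta.get("sampling_rate") or 1.0 / np.median(dt)
        bad = np.nonzero(dt > MAX_GAP_PERIODS / fs)[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-uniform timestamps — gap of {dt[bad[0]]:.4f} s "
                f"after row {int(bad[0])}"
            )
    else:
        fs = meta.get("sampling_rate", 128.0)

    return ImuRecording(
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        sampling_rate=float(fs),
        subject_id=str(meta.get("subject_id", "unknown")),
        group=str(meta.get("group", "unknown")),
        condition=str(meta.get("condition", "usual")),
        bout_id=str(meta.get("bout_id", "0")),
        meta=meta,
    )


def write_step_table(table: StepTable, path: str | Path) -> None:
    table.df.to_csv(Path(path), index=False, float_format="%.6f")


def read_step_table(path: str | Path) -> StepTable:
    """Read a step table CSV; ordering and non-overlap are validated."""
    df = pd.read_csv(Path(path))
    if len(df) == 0:
        return StepTable(pd.DataFrame(columns=["step_index", "start_s", "end_s"]))
    try:
        return StepTable(df)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from err


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Feature matrix CSV plus a JSON sidecar listing feature provenance."""
    from .features import FEATURE_DOC, feature_columns

    path = Path(path)
    matrix.to_csv(path, index=False, float_format="%.9g")
    schema = {
        "features": feature_columns(matrix),
        "families": FEATURE_DOC,
        "target": "target_cm",
        "grouping_key": "subject_id",
    }
    path.with_suffix(".json").write_text(json.dumps(schema, indent=2))


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_report(report, path: str | Path) -> None:
    """Serialize an AgreementReport as JSON and a sibling Markdown table."""
    path = Path(path)
    path.write_text(report.to_json())
    path.with_suffix(".md").write_text(report.to_markdown())
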