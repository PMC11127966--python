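"""Core domain containers shared by every pipeline stage.

Axis convention for the lower-back IMU (fixed throughout the package):
X = mediolateral (ML), Y = vertical, Z = anterior-posterior (AP).
Acceleration is in m/s^2, angular velocity in deg/s, time in seconds,
step lengths externally in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

ACC_COLUMNS = ["ax", "ay", "az"]
GYRO_COLUMNS = ["gx", "gy", "gz"]
SIGNAL_COLUMNS = ["t"] + ACC_COLUMNS + GYRO_COLUMNS

STEP_COLUMNS = ["step_index", "start_s", "end_s", "length_cm"]

#: physiological bounds on a single step duration, seconds
MIN_STEP_DURATION_S = 0.2
MAX_STEP_DURATION_S = 2.0


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented schema."""


class GeometryError(ValueError):
    """Raised when a step length is incompatible with the pendulum geometry."""


@dataclass
class ImuRecording:
    """One subject-trial of synchronized 3D acceleration + angular velocity.

    Parameters
    ----------
    t : array of sample times, seconds, uniformly spaced
    acc : (n, 3) acceleration in m/s^2, columns X (ML), Y (vertical), Z (AP)
    gyro : (n, 3) angular velocity in deg/s, same column order
    sampling_rate : Hz
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sampling_rate: float
    subject_id: str = "unknown"
    group: str = "unknown"
    condition: str = "usual"
    bout_id: str = "0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.shape != (self.t.size, 3) or self.gyro.shape != (self.t.size, 3):
            raise ValueError(
                f"acc/gyro must be (n, 3) with n == len(t); got acc {self.acc.shape}, "
                f"gyro {self.gyro.shape}, n={self.t.size}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def vertical(self) -> np.ndarray:
        """Vertical (Y) acceleration channel, m/s^2."""
        return self.acc[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.t, self.acc, self.gyro]), columns=SIGNAL_COLUMNS
        )

    def copy_with(self, **kwargs) -> "ImuRecording":
        return replace(self, **kwargs)


@dataclass
class FilteredRecording(ImuRecording):
    """An :class:`ImuRecording` after preprocessing, with provenance flags."""

    filter_order: Optional[int] = None
    filter_cutoff_hz: Optional[float] = None
    delay_compensated: bool = False
    gravity_removed: bool = False


@dataclass
class StepTable:
    """Ordered, non-overlapping step events for one or more bouts.

    Backed by a DataFrame with columns ``step_index, start_s, end_s,
    duration_s`` plus optional ``reference_length_cm, estimated_length_cm``
    and the labels ``subject_id, condition, bout_id``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ["step_index", "start_s", "end_s"]:
            if col not in df.columns:
                raise FormatError(f"step table missing required column {col!r}")
        if "duration_s" not in df.columns:
            df["duration_s"] = df["end_s"] - df["start_s"]
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        group_cols = [c for c in ("subject_id", "condition", "bout_id") if c in df.columns]
        grouped = df.groupby(group_cols, sort=False) if group_cols else [(None, df)]
        for _, sub in grouped:
            starts = sub["start_s"].to_numpy()
            ends = sub["end_s"].to_numpy()
            if np.any(ends <= starts):
                raise FormatError("step table contains a non-positive step duration")
            if np.any(starts[1:] < ends[:-1] - 1e-9):
                raise FormatError("step table contains overlapping or unsorted steps")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def durations(self) -> np.ndarray:
        return self.df["duration_s"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start_s"].to_numpy()

    @property
    def reference_lengths(self) -> np.ndarray:
        return self.df["reference_length_cm"].to_numpy()

    def with_estimates(self, estimates_cm: np.ndarray) -> "StepTable":
        df = self.df.copy()
        df["estimated_length_cm"] = np.asarray(estimates_cm, dtype=float)
        return StepTable(df)


def concat_step_tables(tables: list[StepTable]) -> StepTable:
    """Stack step tables from several bouts into one table."""
    if not tables:
        return StepTable(pd.DataFrame(columns=["step_index", "start_s", "end_s"]))
    return StepTable(pd.concat([t.df for t in tables], ignore_index=True))
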