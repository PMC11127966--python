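"""Step detection from the vertical acceleration and reference synchronization.

Initial contacts appear as sharp positive peaks of the (filtered,
gravity-removed) vertical lumbar acceleration.  Detection is
autocorrelation-guided: the dominant step frequency is estimated first and
sets the minimum inter-peak distance, then contacts are local maxima above an
adaptive robust threshold.  Steps are the intervals between consecutive
contacts, pruned to physiological durations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .types import (
    MAX_STEP_DURATION_S,
    MIN_STEP_DURATION_S,
    FilteredRecording,
    ImuRecording,
    StepTable,
)

#: physiological step-frequency band, Hz
STEP_FREQ_BAND = (0.5, 3.3)

#: threshold = median + THRESHOLD_K * scaled MAD
THRESHOLD_K = 0.5
_MAD_SCALE = 1.4826  # consistency factor for Gaussian data

#: minimum inter-peak distance as a fraction of the step period
MIN_PEAK_DISTANCE_FRACTION = 0.6

DEFAULT_SYNC_TOLERANCE_S = 0.25


def estimate_step_frequency(rec: ImuRecording) -> float:
    """Dominant step frequency from the vertical-acceleration autocorrelation.

    Returns the frequency of the first autocorrelation peak inside the
    physiological band; falls back to the band midpoint when the signal has no
    periodic structure.
    """
    y = rec.vertical - rec.vertical.mean()
    fs = rec.sampling_rate
    if np.allclose(y, 0.0):
        return float(np.mean(STEP_FREQ_BAND))
    ac = np.correlate(y, y, mode="full")[y.size - 1 :]
    ac = ac / ac[0]
    lo = max(int(np.floor(fs / STEP_FREQ_BAND[1])), 1)
    hi = min(int(np.ceil(fs / STEP_FREQ_BAND[0])), ac.size - 1)
    if hi <= lo:
        return float(np.mean(STEP_FREQ_BAND))
    band = ac[lo : hi + 1]
    peaks, _ = find_peaks(band)
    if peaks.size == 0:
        lag = lo + int(np.argmax(band))
    else:
        # first sufficiently tall peak in lag order = the step period; the
        # height gate skips small spurious bumps ahead of the fundamental
        tall = peaks[band[peaks] >= 0.5 * band[peaks].max()]
        lag = lo + int(tall[0])
    return float(fs / lag)


def segment_steps(rec: FilteredRecording) -> StepTable:
    """Detect steps as intervals between consecutive initial contacts.

    Requires a gravity-removed recording of at least 2 s.  Returns an empty
    table when no contacts are found.
    """
    if not getattr(rec, "gravity_removed", False):
        raise ValueError("segment_steps requires a gravity-removed recording")
    if rec.duration_s < 2.0:
        raise ValueError("recording must cover at least 2 s for segmentation")

    y = rec.vertical
    fs = rec.sampling_rate
    step_freq = estimate_step_frequency(rec)
    min_dist = max(int(round(MIN_PEAK_DISTANCE_FRACTION / step_freq * fs)), 1)

    med = np.median(y)
    mad = np.median(np.abs(y - med)) * _MAD_SCALE
    height = med + THRESHOLD_K * mad
    peaks, _ = find_peaks(y, height=height, distance=min_dist)

    empty = StepTable(
        pd.DataFrame(
            columns=["step_index", "start_s", "end_s", "duration_s"]
        ).astype(float)
    )
    if peaks.size < 2 or mad == 0.0:
        return empty

    contacts = rec.t[peaks]
    starts = contacts[:-1]
    ends = contacts[1:]
    durations = ends - starts
    keep = (durations >= MIN_STEP_DURATION_S) & (durations <= MAX_STEP_DURATION_S)
    starts, ends, durations = starts[keep], ends[keep], durations[keep]
    if starts.size == 0:
        return empty
    return StepTable(
        pd.DataFrame(
            {
                "step_index": np.arange(starts.size),
                "start_s": starts,
                "end_s": ends,
                "duration_s": durations,
                "subject_id": rec.subject_id,
                "group": rec.group,
                "condition": rec.condition,
                "bout_id": rec.bout_id,
            }
        )
    )


def synchronize(
    detected: StepTable,
    reference: StepTable,
    tolerance_s: float = DEFAULT_SYNC_TOLERANCE_S,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of detected to reference steps.

    Candidate pairs are taken in order of increasing absolute start-time
    difference (ties resolved toward the earlier reference step); each step
    joins at most one pair, and pairs farther apart than ``tolerance_s`` are
    discarded.  Returns ``(detected_row, reference_row, offset_s)`` triples
    where offset = detected start - reference start.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be non-negative")
    det = detected.df["start_s"].to_numpy()
    ref = reference.df["start_s"].to_numpy()
    if det.size == 0 or ref.size == 0:
        return []
    diff = np.abs(det[:, None] - ref[None, :])
    order = np.argsort(diff, axis=None, kind="stable")  # stable: earlier ref wins ties
    used_det = np.zeros(det.size, dtype=bool)
    used_ref = np.zeros(ref.size, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for flat in order:
        i, j = np.unravel_index(flat, diff.shape)
        if diff[i, j] > tolerance_s:
            break
        if used_det[i] or used_ref[j]:
            continue
        used_det[i] = True
        used_ref[j] = True
        pairs.append((int(i), int(j), float(det[i] - ref[j])))
    pairs.sort(key=lambda p: p[1])
    return pairs


def attach_reference_lengths(
    detected: StepTable,
    reference: StepTable,
    tolerance_s: float = DEFAULT_SYNC_TOLERANCE_S,
) -> StepTable:
    """Copy reference lengths onto matched detected steps; drop unmatched ones."""
    pairs = synchronize(detected, reference, tolerance_s)
    if not pairs:
        return StepTable(detected.df.iloc[0:0].copy())
    det_rows = [p[0] for p in pairs]
    ref_rows = [p[1] for p in pairs]
    df = detected.df.iloc[det_rows].copy().reset_index(drop=True)
    df["reference_length_cm"] = (
        reference.df["reference_length_cm"].to_numpy()[ref_rows]
    )
    df = df.sort_values("start_s").reset_index(drop=True)
    df["step_index"] = np.arange(len(df))
    return StepTable(df)
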