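"""Signal conditioning: zero-phase FIR low-pass filtering and gravity removal.

The filter is a linear-phase windowed-sinc (Hamming) FIR, order 101 at
128 Hz, applied by symmetric convolution with reflection padding so the group
delay is fully compensated and event timing is preserved.  Gravity is removed
by per-bout mean subtraction per channel — a deliberately calibration-free
choice that matches a single, arbitrarily-oriented lower-back sensor.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import firwin

from .types import FilteredRecording, ImuRecording

DEFAULT_CUTOFF_HZ = 20.0
DEFAULT_NUMTAPS = 101


def design_lowpass(cutoff_hz: float, sampling_rate: float, numtaps: int = DEFAULT_NUMTAPS) -> np.ndarray:
    """Design the windowed-sinc low-pass taps (Hamming window, unit DC gain)."""
    if cutoff_hz >= sampling_rate / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{sampling_rate / 2.0} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return firwin(numtaps, cutoff_hz, fs=sampling_rate, window="hamming")


def _filter_channel(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR application: reflect-pad, convolve centered, crop."""
    pad = len(taps)  # generous: >= (numtaps - 1) // 2 on each side
    if x.size < 2:
        return x.copy()
    padded = np.pad(x, pad, mode="reflect")
    out = np.convolve(padded, taps, mode="same")
    return out[pad:-pad]


def lowpass_filter(
    rec: ImuRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    numtaps: int = DEFAULT_NUMTAPS,
) -> FilteredRecording:
    """Low-pass filter all six channels with delay compensation.

    Output length equals input length; edges use reflection padding.
    """
    taps = design_lowpass(cutoff_hz, rec.sampling_rate, numtaps)
    acc = np.column_stack([_filter_channel(rec.acc[:, i], taps) for i in range(3)])
    gyro = np.column_stack([_filter_channel(rec.gyro[:, i], taps) for i in range(3)])
    return FilteredRecording(
        t=rec.t,
        acc=acc,
        gyro=gyro,
        sampling_rate=rec.sampling_rate,
        subject_id=rec.subject_id,
        group=rec.group,
        condition=rec.condition,
        bout_id=rec.bout_id,
        meta=dict(rec.meta),
        filter_order=numtaps - 1,
        filter_cutoff_hz=cutoff_hz,
        delay_compensated=True,
        gravity_removed=getattr(rec, "gravity_removed", False),
    )


def remove_gravity(rec: ImuRecording) -> FilteredRecording:
    """Subtract the per-bout mean from every acceleration channel.

    After this the vertical channel is zero-mean, as required before double
    integration.  Idempotent.
    """
    if rec.duration_s < 1.0:
        raise ValueError("gravity removal needs at least 1 s of signal")
    acc = rec.acc - rec.acc.mean(axis=0, keepdims=True)
    return FilteredRecording(
        t=rec.t,
        acc=acc,
        gyro=rec.gyro.copy(),
        sampling_rate=rec.sampling_rate,
        subject_id=rec.subject_id,
        group=rec.group,
        condition=rec.condition,
        bout_id=rec.bout_id,
        meta=dict(rec.meta),
        filter_order=getattr(rec, "filter_order", None),
        filter_cutoff_hz=getattr(rec, "filter_cutoff_hz", None),
        delay_compensated=getattr(rec, "delay_compensated", False),
        gravity_removed=True,
    )


def preprocess(rec: ImuRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> FilteredRecording:
    """Standard conditioning chain: low-pass filter then gravity removal."""
    return remove_gravity(lowpass_filter(rec, cutoff_hz))
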