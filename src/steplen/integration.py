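"""Double integration of acceleration over a step window with drift control.

Lumbar accelerometry cannot use zero-velocity updates (no stance-phase rest at
the lower back), so drift is controlled per step by a boundary-anchored linear
velocity correction: the vertical velocity of the center of mass is taken to
be zero at each initial contact, and the line through the integrated
velocity's endpoint values is subtracted.  For a drift caused by a constant
acceleration bias this removes the drift exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid


def window_samples(
    t: np.ndarray, x: np.ndarray, t0: float, t1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of x on [t0, t1] with interpolated values at the exact bounds.

    Interpolating the window edges (rather than rounding them to the grid)
    keeps per-step integrals insensitive to where the step boundaries fall
    between samples.
    """
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    inside = (t > t0) & (t < t1)
    tw = np.concatenate([[t0], t[inside], [t1]])
    xw = np.concatenate([[np.interp(t0, t, x)], x[inside], [np.interp(t1, t, x)]])
    return tw, xw


def integrate_window(
    t: np.ndarray,
    a: np.ndarray,
    t0: float,
    t1: float,
    detrend_velocity: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Double-integrate acceleration over [t0, t1] with zero initial conditions.

    Returns ``(tw, velocity, displacement)`` on the window grid.  When
    ``detrend_velocity`` is set, the line through the velocity's first and
    last values is subtracted before the second integration (endpoint-anchored
    linear detrend).
    """
    tw, aw = window_samples(t, a, t0, t1)
    if tw.size < 3:
        raise ValueError("window too short to integrate (need >= 3 samples)")
    v = cumulative_trapezoid(aw, tw, initial=0.0)
    if detrend_velocity:
        slope = (v[-1] - v[0]) / (tw[-1] - tw[0])
        v = v - (v[0] + slope * (tw - tw[0]))
    d = cumulative_trapezoid(v, tw, initial=0.0)
    return tw, v, d


def net_displacement(
    t: np.ndarray, a: np.ndarray, t0: float, t1: float, detrend_velocity: bool = True
) -> float:
    """Displacement accumulated over the window (final minus initial)."""
    _, _, d = integrate_window(t, a, t0, t1, detrend_velocity)
    return float(d[-1] - d[0])


def displacement_range(
    t: np.ndarray, a: np.ndarray, t0: float, t1: float, detrend_velocity: bool = True
) -> float:
    """Peak-to-peak displacement over the window (max minus min)."""
    _, _, d = integrate_window(t, a, t0, t1, detrend_velocity)
    return float(d.max() - d.min())
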