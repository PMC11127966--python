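"""Synthetic lower-back IMU walking signals with exactly known step tables.

The vertical channel of each simulated bout is built from an inverted-pendulum
model of the center of mass (CoM): during a step of length ``S`` (m) taken over
an effective pendulum (leg) length ``l`` (m), the CoM rises by

    h = l - sqrt(l^2 - (S/2)^2)

between initial contact (CoM lowest) and mid-stance (CoM highest).  The
simulator realizes this as a per-step raised-cosine vertical trajectory

    y(t) = -(h/2) * cos(2*pi*t/D),   t in [0, D]

(zero vertical velocity at the contacts, peak-to-trough excursion exactly h,
peak positive acceleration at each contact) whose second time-derivative is
emitted as the vertical acceleration, so a double integration of the
noiseless vertical channel recovers ``h`` exactly up to discretization error.
A short zero-moment burst is superposed at every initial contact as a
heel-strike landmark; gravity rides on the vertical channel as a constant
+9.81 m/s^2.

Conditions rescale the per-subject gait: ``fast`` lengthens and quickens
steps, ``dual-task`` shortens them and inflates variability, mirroring the
usual/fast/dual-task contrasts seen on instrumented walkways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import GeometryError, ImuRecording, StepTable

GRAVITY_M_S2 = 9.81
CONDITIONS = ("usual", "fast", "dual-task")
GROUPS = ("PD-like", "MCI-like", "OA-like", "HC-like", "MS-like")

#: condition multipliers applied to (step length, step duration, variability)
CONDITION_EFFECTS: Mapping[str, tuple[float, float, float]] = {
    "usual": (1.00, 1.00, 1.0),
    "fast": (1.10, 0.92, 1.0),
    "dual-task": (0.93, 1.00, 1.3),
}

#: heel-strike transient amplitude relative to the pendulum-arc peak
#: acceleration of the step it starts (the stencil itself spans 5 samples,
#: about 40 ms at 128 Hz)
TRANSIENT_RELATIVE_AMPLITUDE = 1.5

#: quiet standing padding before the first and after the last contact, s
LEAD_S = 0.5

#: effective pendulum length as a fraction of body height (anthropometric)
PENDULUM_HEIGHT_FRACTION = 0.53


@dataclass
class SubjectSpec:
    """Gait parameters of one simulated subject.

    Lengths are in cm (matching walkway reporting); the pendulum length is in
    meters.  ``asymmetry`` is the fractional left/right step-length offset:
    odd steps are scaled by (1 + asymmetry/2), even steps by (1 - asymmetry/2).
    """

    subject_id: str
    group: str = "HC-like"
    mean_step_length: float = 60.0
    step_length_sd: float = 2.5
    mean_step_duration: float = 0.55
    step_duration_sd: float = 0.02
    pendulum_length: float = 0.88
    asymmetry: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.mean_step_length <= 0:
            raise ValueError("mean_step_length must be positive")
        if self.step_length_sd < 0 or self.step_duration_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mean_step_duration <= 0:
            raise ValueError("mean_step_duration must be positive")
        if self.pendulum_length <= 0:
            raise ValueError("pendulum_length must be positive")
        if self.mean_step_length / 100.0 >= 2.0 * self.pendulum_length:
            raise GeometryError(
                "mean step length exceeds the pendulum chord limit "
                f"(S={self.mean_step_length} cm, 2l={200 * self.pendulum_length} cm)"
            )


@dataclass
class GroupSpec:
    """Group-level distributions from which SubjectSpec draws are made."""

    group: str
    n_subjects: int
    mean_step_length: float = 57.0  # cm, population mean
    between_subject_sd: float = 10.0  # cm, spread of subject means
    step_length_sd: float = 2.5  # cm, within-subject step-to-step sd
    mean_step_duration: float = 0.55  # s
    between_subject_duration_sd: float = 0.05  # s
    step_duration_sd: float = 0.02  # s
    height_mean: float = 1.66  # m
    height_sd: float = 0.09  # m
    noise_sd: float = 0.0  # m/s^2


#: default group-level gait distributions; step-length means follow the usual
#: ordering clinically observed across these populations
DEFAULT_GROUP_PARAMS: Mapping[str, dict] = {
    "PD-like": dict(mean_step_length=56.0, height_mean=1.68, step_length_sd=3.5),
    "MCI-like": dict(mean_step_length=55.8, height_mean=1.63, step_length_sd=3.0),
    "OA-like": dict(mean_step_length=57.5, height_mean=1.63, step_length_sd=2.5),
    "HC-like": dict(mean_step_length=79.0, height_mean=1.70, step_length_sd=2.5),
    "MS-like": dict(mean_step_length=68.5, height_mean=1.69, step_length_sd=3.0),
}


@dataclass
class CohortSpec:
    """A cohort to simulate: subjects x conditions x bouts."""

    subjects: Sequence[SubjectSpec] = ()
    groups: Sequence[GroupSpec] = ()
    conditions: Sequence[str] = ("usual",)
    n_steps_per_bout: int = 20
    bouts_per_condition: int = 1
    sampling_rate: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 64:
            raise ValueError("sampling_rate must be >= 64 Hz")
        if self.n_steps_per_bout < 2:
            raise ValueError("n_steps_per_bout must be >= 2")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        if not self.subjects and not self.groups:
            raise ValueError("cohort needs subjects or group distributions")


def pendulum_vertical_excursion(step_length_m: float, pendulum_length: float) -> float:
    """CoM vertical excursion h = l - sqrt(l^2 - (S/2)^2) for one step."""
    half = step_length_m / 2.0
    if half >= pendulum_length:
        raise GeometryError(
            f"step length {step_length_m} m exceeds pendulum chord limit "
            f"2l = {2 * pendulum_length} m"
        )
    return pendulum_length - np.sqrt(pendulum_length**2 - half**2)


#: heel-strike transient stencil, centered on the contact sample.  The shape
#: is triphasic (sharp positive spike flanked by negative lobes) and is
#: designed directly in discrete time so that, under trapezoidal integration
#: on the sample grid, each half of the stencil contributes exactly zero net
#: velocity and zero net displacement to the step window it falls in — the
#: impact landmark is invisible to per-step double integration.  Its energy
#: sits near the Nyquist band, mimicking a real impact transient that a 20 Hz
#: low-pass largely removes.
HEEL_STRIKE_STENCIL = np.array([0.25, -0.75, 1.0, -0.75, 0.25])


def _add_heel_strike(ay: np.ndarray, center_idx: int, amplitude: float) -> None:
    """Superpose the heel-strike stencil (peak ``amplitude``) at a contact sample."""
    half = len(HEEL_STRIKE_STENCIL) // 2
    lo = center_idx - half
    hi = center_idx + half + 1
    s_lo = max(0, -lo)
    s_hi = len(HEEL_STRIKE_STENCIL) - max(0, hi - ay.size)
    ay[max(lo, 0) : min(hi, ay.size)] += amplitude * HEEL_STRIKE_STENCIL[s_lo:s_hi]


def simulate_bout(
    subject: SubjectSpec,
    condition: str = "usual",
    n_steps: int = 20,
    sampling_rate: float = 128.0,
    seed: int = 0,
    bout_id: str = "0",
) -> tuple[ImuRecording, StepTable]:
    """Simulate one straight-line walking bout.

    Returns the 6-channel recording and the ground-truth step table (one row
    per step with exact start/end time and true length in cm).  Output is a
    pure function of the arguments: the same spec and seed give bit-identical
    results.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if condition not in CONDITION_EFFECTS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = np.random.default_rng(seed)
    len_mult, dur_mult, var_mult = CONDITION_EFFECTS[condition]

    mean_len = subject.mean_step_length * len_mult
    sd_len = subject.step_length_sd * var_mult
    mean_dur = subject.mean_step_duration * dur_mult
    sd_dur = subject.step_duration_sd * var_mult

    lengths_cm = rng.normal(mean_len, sd_len, size=n_steps)
    lengths_cm = np.clip(lengths_cm, 10.0, None)
    if subject.asymmetry:
        side = np.where(np.arange(n_steps) % 2 == 0, 1.0, -1.0)
        lengths_cm = lengths_cm * (1.0 + side * subject.asymmetry / 2.0)
    durations = rng.normal(mean_dur, sd_dur, size=n_steps)
    durations = np.clip(durations, 0.25, 1.9)
    # contacts land exactly on the sample grid (the walkway reference and the
    # IMU share one clock); sub-sample contact phase would otherwise dominate
    # the numerical error of per-step integration
    durations = np.round(durations * sampling_rate) / sampling_rate

    l = subject.pendulum_length
    if np.any(lengths_cm / 100.0 >= 2.0 * l):
        bad = float(np.max(lengths_cm))
        raise GeometryError(
            f"drawn step length {bad:.1f} cm exceeds pendulum chord limit "
            f"2l = {200 * l:.1f} cm"
        )
    excursions = np.array(
        [pendulum_vertical_excursion(s / 100.0, l) for s in lengths_cm]
    )

    starts = LEAD_S + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    ends = starts + durations
    total_s = ends[-1] + LEAD_S
    n_samples = int(np.floor(total_s * sampling_rate)) + 1
    t = np.arange(n_samples) / sampling_rate

    ay = np.zeros(n_samples)
    n_last = len(starts) - 1
    for k, (start, dur, h) in enumerate(zip(starts, durations, excursions)):
        # contacts are grid-aligned; each step's arc is rendered on its closed
        # sample range with half weight at shared interior contact samples, so
        # those samples hold the mean of the two adjacent arcs' limits (the
        # correct trapezoidal value for the acceleration jump at that node)
        i0 = int(round(start * sampling_rate))
        i1 = min(int(round((start + dur) * sampling_rate)), n_samples - 1)
        omega = 2.0 * np.pi / dur
        vals = (h / 2.0) * omega**2 * np.cos(omega * (t[i0 : i1 + 1] - start))
        if k > 0:
            vals[0] *= 0.5
        if k < n_last:
            vals[-1] *= 0.5
        ay[i0 : i1 + 1] += vals

    # heel-strike landmark at every initial contact, including the terminal one
    arc_peaks = excursions / 2.0 * (2.0 * np.pi / durations) ** 2
    contacts = np.concatenate([starts, [ends[-1]]])
    peaks_at_contacts = np.concatenate([arc_peaks, [arc_peaks[-1]]])
    for contact, peak in zip(contacts, peaks_at_contacts):
        _add_heel_strike(
            ay,
            int(round(contact * sampling_rate)),
            TRANSIENT_RELATIVE_AMPLITUDE * peak,
        )

    # ML / AP channels: low-amplitude step- and stride-frequency oscillations
    step_freq = 1.0 / float(np.mean(durations))
    walking = (t >= starts[0]) & (t < ends[-1])
    ax = np.zeros(n_samples)
    az = np.zeros(n_samples)
    # ML sway at stride frequency, AP progression oscillation at step frequency;
    # amplitudes scale with the vertical arc so the side channels carry length
    # information too
    arc_scale = float(np.mean(arc_peaks))
    ax[walking] = 0.3 * arc_scale * np.sin(np.pi * step_freq * (t[walking] - starts[0]))
    az[walking] = 0.5 * arc_scale * np.sin(2.0 * np.pi * step_freq * (t[walking] - starts[0]))

    acc = np.column_stack([ax, ay + GRAVITY_M_S2, az])
    if subject.noise_sd > 0:
        acc = acc + rng.normal(0.0, subject.noise_sd, size=acc.shape)

    # pelvis-rotation proxy: deg/s sinusoids at step and stride frequency
    gyro = np.zeros((n_samples, 3))
    gyro[walking, 0] = 2.0 * np.sin(np.pi * step_freq * (t[walking] - starts[0]))
    gyro[walking, 1] = 4.0 * np.sin(np.pi * step_freq * (t[walking] - starts[0]))
    gyro[walking, 2] = 3.0 * np.sin(2.0 * np.pi * step_freq * (t[walking] - starts[0]))
    if subject.noise_sd > 0:
        gyro = gyro + rng.normal(0.0, subject.noise_sd, size=gyro.shape)

    table = StepTable(
        pd.DataFrame(
            {
                "step_index": np.arange(n_steps),
                "start_s": starts,
                "end_s": ends,
                "duration_s": durations,
                "reference_length_cm": lengths_cm,
                "subject_id": subject.subject_id,
                "group": subject.group,
                "condition": condition,
                "bout_id": bout_id,
            }
        )
    )
    rec = ImuRecording(
        t=t,
        acc=acc,
        gyro=gyro,
        sampling_rate=sampling_rate,
        subject_id=subject.subject_id,
        group=subject.group,
        condition=condition,
        bout_id=bout_id,
        meta={"pendulum_length_m": l, "noise_sd": subject.noise_sd},
    )
    return rec, table


def draw_subjects(groups: Iterable[GroupSpec], rng: np.random.Generator) -> list[SubjectSpec]:
    """Draw per-subject gait parameters from group-level distributions."""
    subjects = []
    for g in groups:
        for i in range(g.n_subjects):
            height = rng.normal(g.height_mean, g.height_sd)
            height = float(np.clip(height, 1.40, 2.05))
            mean_len = rng.normal(g.mean_step_length, g.between_subject_sd)
            mean_len = float(np.clip(mean_len, 25.0, 95.0))
            mean_dur = rng.normal(g.mean_step_duration, g.between_subject_duration_sd)
            mean_dur = float(np.clip(mean_dur, 0.35, 1.2))
            subjects.append(
                SubjectSpec(
                    subject_id=f"{g.group}-{i:03d}",
                    group=g.group,
                    mean_step_length=mean_len,
                    step_length_sd=g.step_length_sd,
                    mean_step_duration=mean_dur,
                    step_duration_sd=g.step_duration_sd,
                    pendulum_length=PENDULUM_HEIGHT_FRACTION * height,
                    noise_sd=g.noise_sd,
                )
            )
    return subjects


def simulate_cohort(spec: CohortSpec) -> dict[tuple[str, str, str], tuple[ImuRecording, StepTable]]:
    """Simulate every (subject, condition, bout) of a cohort.

    Each bout uses an independent substream spawned from the master seed, so
    adding subjects or conditions never perturbs the draws of others.
    """
    master = np.random.default_rng(spec.seed)
    subjects = list(spec.subjects)
    if spec.groups:
        subjects = subjects + draw_subjects(spec.groups, master)
    if not subjects:
        raise ValueError("cohort contains no subjects")

    seed_seq = np.random.SeedSequence(spec.seed)
    n_bouts = len(subjects) * len(spec.conditions) * spec.bouts_per_condition
    children = seed_seq.spawn(n_bouts)

    out: dict[tuple[str, str, str], tuple[ImuRecording, StepTable]] = {}
    k = 0
    for subj in subjects:
        for cond in spec.conditions:
            for b in range(spec.bouts_per_condition):
                bout_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
                k += 1
                out[(subj.subject_id, cond, str(b))] = simulate_bout(
                    subj,
                    condition=cond,
                    n_steps=spec.n_steps_per_bout,
                    sampling_rate=spec.sampling_rate,
                    seed=bout_seed,
                    bout_id=str(b),
                )
    return out


def cohort_sidecar(rec: ImuRecording) -> str:
    """JSON sidecar describing a recording's provenance."""
    return json.dumps(
        {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "condition": rec.condition,
            "bout_id": rec.bout_id,
            "sampling_rate": rec.sampling_rate,
            "axes": {"x": "mediolateral", "y": "vertical", "z": "anterior-posterior"},
            "units": {"acc": "m/s^2", "gyro": "deg/s", "t": "s"},
        },
        indent=2,
    )
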