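"""Per-step and fixed-window feature extraction, and forward stepwise selection.

Feature families (all computed from the gravity-removed acceleration):

* time-domain statistics (mean, sd, min, max, range, RMS) per axis and for
  the Euclidean magnitude;
* FFT amplitude coefficients per acceleration axis — steps are first
  resampled to a fixed 128-sample grid so coefficients are comparable across
  variable-duration steps; coefficient 0 equals the window mean, coefficients
  k >= 1 are single-sided amplitudes 2|X_k|/N;
* acceleration-magnitude energy: mean squared Euclidean norm;
* double-integration displacements of the mediolateral (X) and vertical (Y)
  axes — net displacement and peak-to-peak excursion, with an
  endpoint-anchored linear velocity detrend as drift control;
* step (or window) duration.

Feature names are stable; see ``FEATURE_DOC`` for provenance of each family.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import models
from .integration import displacement_range, net_displacement
from .types import FilteredRecording, StepTable
from .validation import grouped_cv_split

FFT_GRID_SAMPLES = 128
N_FFT_COEFFICIENTS = 10

#: metadata columns of a feature matrix; everything else is a feature
META_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "bout_id",
    "step_index",
    "start_s",
    "end_s",
    "duration_s",
    "target_cm",
]

FEATURE_DOC = {
    "stat": "per-axis and magnitude time-domain statistics over the segment",
    "fft": "single-sided FFT amplitudes on a fixed 128-sample resampled grid",
    "energy": "mean squared Euclidean norm of the 3D acceleration",
    "disp": "double-integrated ML/vertical displacement with anchored velocity detrend",
    "duration": "segment duration in seconds",
}

_AXES = {"ml": 0, "v": 1, "ap": 2}


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature matrix."""
    return [c for c in df.columns if c not in META_COLUMNS]


def _fft_amplitudes(x: np.ndarray, n_coeff: int) -> np.ndarray:
    """First ``n_coeff`` single-sided FFT amplitudes; index 0 is the mean."""
    n = x.size
    spec = np.fft.rfft(x) / n
    amps = np.abs(spec)
    amps[1:] *= 2.0
    amps[0] = spec[0].real  # signed mean, exact for constant signals
    out = np.zeros(n_coeff)
    take = min(n_coeff, amps.size)
    out[:take] = amps[:take]
    return out


def extract_segment_features(
    t: np.ndarray,
    acc: np.ndarray,
    t0: float,
    t1: float,
    resample_fft: bool = True,
    detrend_velocity: bool = True,
) -> dict[str, float]:
    """Feature mapping for one segment [t0, t1] of a 3-axis acceleration."""
    inside = (t >= t0) & (t < t1)
    if inside.sum() < 3:
        raise ValueError(
            f"degenerate segment [{t0:.3f}, {t1:.3f}] s: fewer than 3 samples"
        )
    seg = acc[inside]
    mag = np.linalg.norm(seg, axis=1)

    feats: dict[str, float] = {}
    channels = {"ml": seg[:, 0], "v": seg[:, 1], "ap": seg[:, 2], "mag": mag}
    for name, x in channels.items():
        feats[f"stat_{name}_mean"] = float(x.mean())
        feats[f"stat_{name}_sd"] = float(x.std(ddof=0))
        feats[f"stat_{name}_min"] = float(x.min())
        feats[f"stat_{name}_max"] = float(x.max())
        feats[f"stat_{name}_range"] = float(x.max() - x.min())
        feats[f"stat_{name}_rms"] = float(np.sqrt(np.mean(x**2)))

    for name in ("ml", "v", "ap"):
        x = channels[name]
        if resample_fft and x.size != FFT_GRID_SAMPLES:
            grid = np.linspace(0.0, 1.0, FFT_GRID_SAMPLES)
            pos = np.linspace(0.0, 1.0, x.size)
            x = np.interp(grid, pos, x)
        amps = _fft_amplitudes(x, N_FFT_COEFFICIENTS)
        for k in range(N_FFT_COEFFICIENTS):
            feats[f"fft_{name}_{k}"] = float(amps[k])

    feats["energy_mag"] = float(np.mean(mag**2))

    for name in ("ml", "v"):
        a = acc[:, _AXES[name]]
        feats[f"disp_net_{name}"] = net_displacement(t, a, t0, t1, detrend_velocity)
        feats[f"disp_range_{name}"] = displacement_range(t, a, t0, t1, detrend_velocity)

    feats["duration"] = float(t1 - t0)
    return feats


def extract_step_features(
    rec: FilteredRecording,
    start_s: float,
    end_s: float,
    detrend_velocity: bool = True,
) -> dict[str, float]:
    """Feature mapping for one segmented step of a gravity-removed recording."""
    return extract_segment_features(
        rec.t, rec.acc, start_s, end_s, resample_fft=True, detrend_velocity=detrend_velocity
    )


def build_step_feature_matrix(
    rec: FilteredRecording, steps: StepTable
) -> pd.DataFrame:
    """One feature row per step; target is the step's reference length (cm)."""
    rows = []
    for _, step in steps.df.iterrows():
        feats = extract_step_features(rec, float(step["start_s"]), float(step["end_s"]))
        feats.update(
            subject_id=step.get("subject_id", rec.subject_id),
            group=step.get("group", rec.group),
            condition=step.get("condition", rec.condition),
            bout_id=step.get("bout_id", rec.bout_id),
            step_index=int(step["step_index"]),
            start_s=float(step["start_s"]),
            end_s=float(step["end_s"]),
            duration_s=float(step["end_s"] - step["start_s"]),
            target_cm=float(step.get("reference_length_cm", np.nan)),
        )
        rows.append(feats)
    return pd.DataFrame(rows)


def window_target_cm(reference: StepTable, t0: float, t1: float) -> float:
    """Reference distance traveled in [t0, t1]: overlapping step lengths,
    edge steps pro-rated by time overlap."""
    total = 0.0
    for _, step in reference.df.iterrows():
        overlap = min(t1, step["end_s"]) - max(t0, step["start_s"])
        if overlap <= 0:
            continue
        frac = overlap / (step["end_s"] - step["start_s"])
        total += frac * float(step["reference_length_cm"])
    return total


def extract_window_features(
    rec: FilteredRecording,
    reference: StepTable,
    window_length_s: float,
    n_windows: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature rows for seeded random fixed-duration windows within the bout.

    Targets are reference distances traveled in each window (cm).  Windows are
    drawn inside the walking portion of the bout (first to last reference
    step) so every window overlaps actual walking.
    """
    ref = reference.df
    if len(ref) == 0:
        raise ValueError("window extraction needs a non-empty reference table")
    walk_start = float(ref["start_s"].min())
    walk_end = float(ref["end_s"].max())
    if window_length_s >= walk_end - walk_start:
        raise ValueError(
            f"window of {window_length_s} s exceeds the walking bout "
            f"({walk_end - walk_start:.2f} s)"
        )
    rng = np.random.default_rng(seed)
    starts = rng.uniform(walk_start, walk_end - window_length_s, size=n_windows)
    rows = []
    for i, t0 in enumerate(np.sort(starts)):
        t1 = t0 + window_length_s
        feats = extract_segment_features(
            rec.t, rec.acc, t0, t1, resample_fft=False, detrend_velocity=True
        )
        feats.update(
            subject_id=rec.subject_id,
            group=rec.group,
            condition=rec.condition,
            bout_id=rec.bout_id,
            step_index=i,
            start_s=float(t0),
            end_s=float(t1),
            duration_s=float(window_length_s),
            target_cm=window_target_cm(reference, t0, t1),
        )
        rows.append(feats)
    return pd.DataFrame(rows)


class ForwardStepwiseSelector(BaseEstimator):
    """Greedy forward feature selection scored by subject-wise CV RMSE.

    At each iteration every remaining candidate is scored by the
    cross-validated RMSE of ``model_family`` on the current set plus the
    candidate; the best candidate is added if it strictly lowers the RMSE
    (ties break by feature-name order).  Selection stops at ``max_features``
    or when no candidate improves.

    Attributes
    ----------
    selected_features_ : list of str, in selection order
    rmse_path_ : CV RMSE after each accepted feature (non-increasing)
    """

    def __init__(
        self,
        model_family: str = "lr",
        max_features: int = 34,
        n_folds: int = 5,
        seed: int = 0,
        hyper: Optional[dict] = None,
    ):
        self.model_family = model_family
        self.max_features = max_features
        self.n_folds = n_folds
        self.seed = seed
        self.hyper = hyper

    def _cv_rmse(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        cols: list[str],
        fold_of: dict[str, int],
        groups: np.ndarray,
    ) -> float:
        errs = []
        folds = sorted(set(fold_of.values()))
        for f in folds:
            test = np.array([fold_of[g] == f for g in groups])
            if test.all() or not test.any():
                continue
            model = models.make_model_for_grid_point(
                self.model_family, self.seed, self.hyper or {}
            )
            model.fit(X.loc[~test, cols].to_numpy(), y[~test])
            pred = model.predict(X.loc[test, cols].to_numpy())
            errs.append((pred - y[test]) ** 2)
        return float(np.sqrt(np.mean(np.concatenate(errs))))

    def fit(self, X: pd.DataFrame, y=None, groups=None):
        """Select features from a feature matrix.

        ``X`` may be a full feature matrix (with META_COLUMNS, in which case
        ``y``/``groups`` default to its target and subject columns) or a plain
        feature frame with explicit ``y`` and ``groups``.
        """
        if y is None:
            y = X["target_cm"].to_numpy()
        else:
            y = np.asarray(y, dtype=float)
        if groups is None:
            groups = X["subject_id"].to_numpy()
        else:
            groups = np.asarray(groups)
        cols = feature_columns(X)
        if len(cols) < 2:
            raise ValueError("stepwise selection needs at least 2 features")
        Xf = X[cols]
        if not np.all(np.isfinite(Xf.to_numpy())) or not np.all(np.isfinite(y)):
            raise ValueError("feature matrix contains non-finite values")
        max_features = min(self.max_features, len(cols))

        n_subjects = len(set(groups.tolist()))
        k = min(self.n_folds, n_subjects)
        if k < 2:
            raise ValueError("stepwise selection needs >= 2 subjects")
        fold_of = grouped_cv_split(groups.tolist(), k=k, seed=self.seed)

        selected: list[str] = []
        remaining = sorted(cols)
        best_rmse = np.inf
        path: list[float] = []
        while remaining and len(selected) < max_features:
            scores = {
                cand: self._cv_rmse(Xf, y, selected + [cand], fold_of, groups)
                for cand in remaining
            }
            # strict improvement required; iteration in name order breaks ties
            best_cand, best_score = None, best_rmse
            for cand in remaining:
                if scores[cand] < best_score:
                    best_cand, best_score = cand, scores[cand]
            if best_cand is None:
                break
            selected.append(best_cand)
            remaining.remove(best_cand)
            best_rmse = best_score
            path.append(best_score)

        self.selected_features_ = selected
        self.rmse_path_ = path
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


def stepwise_select(
    matrix: pd.DataFrame,
    model_family: str = "lr",
    max_features: int = 34,
    n_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Functional wrapper over :class:`ForwardStepwiseSelector`."""
    sel = ForwardStepwiseSelector(
        model_family=model_family, max_features=max_features, n_folds=n_folds, seed=seed
    )
    sel.fit(matrix)
    return sel.selected_features_
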