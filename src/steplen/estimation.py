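"""Step-length estimators: the regression zoo, the inverted-pendulum baseline,
n-step averaging, and gait-speed derivation.

The regression core is the contribution: per-step features from a single
lower-back IMU are mapped to step length (cm) by one of five model families,
with hyper-parameters grid-searched per cross-validation fold on that fold's
training subjects only.  The inverted-pendulum baseline converts the vertical
center-of-mass excursion h recovered by double integration into a step length
through the chord relation  S = 2 * sqrt(2*l*h - h^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import models
from .features import feature_columns
from .integration import integrate_window
from .types import FilteredRecording, StepTable
from .validation import check_no_leakage, grouped_cv_split

#: sanity envelope for predicted step lengths, cm
PREDICTION_CLIP_CM = (5.0, 150.0)


def clip_predictions(pred_cm: np.ndarray) -> np.ndarray:
    """Clamp predictions to the physiological envelope [5, 150] cm."""
    return np.clip(pred_cm, *PREDICTION_CLIP_CM)


class StepLengthRegressor(BaseEstimator, RegressorMixin):
    """Per-step step-length regression with inner subject-wise model selection.

    Parameters
    ----------
    model_family : one of {"lr", "tree", "svm", "knn", "gbt"}
    hyper_grid : mapping of hyper-parameter name to candidate values; defaults
        to the family's documented grid.  A single-point grid skips the search.
    n_inner_folds : folds of the inner subject-wise CV used for the search
    seed : controls fold shuffling and any stochastic model internals

    Attributes
    ----------
    best_params_ : hyper-parameters chosen by the inner search
    model_ : the refitted underlying model
    feature_names_ : column order the model expects
    """

    def __init__(
        self,
        model_family: str = "gbt",
        hyper_grid: Optional[dict] = None,
        n_inner_folds: int = 3,
        seed: int = 0,
        clip_cm: Optional[tuple] = PREDICTION_CLIP_CM,
    ):
        self.model_family = model_family
        self.hyper_grid = hyper_grid
        self.n_inner_folds = n_inner_folds
        self.seed = seed
        self.clip_cm = clip_cm

    def _as_frame(self, X, feature_names=None) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        names = feature_names or [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=names)

    def fit(self, X, y, groups=None):
        Xf = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(Xf) != y.size:
            raise ValueError("X and y disagree on the number of rows")
        if not np.all(np.isfinite(Xf.to_numpy())) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in training data")
        grid = self.hyper_grid if self.hyper_grid is not None else models.DEFAULT_GRIDS[
            self.model_family
        ]
        points = models.grid_points(grid)

        if len(points) > 1 and groups is not None:
            groups = np.asarray(groups)
            subjects = list(dict.fromkeys(groups.tolist()))
            if len(subjects) < 2:
                raise ValueError("hyper-parameter search needs >= 2 training subjects")
            k = min(self.n_inner_folds, len(subjects))
            fold_of = grouped_cv_split(groups.tolist(), k=k, seed=self.seed)
            best_point, best_rmse = points[0], np.inf
            for point in points:
                sq = []
                for f in range(k):
                    test = np.array([fold_of[g] == f for g in groups])
                    if test.all() or not test.any():
                        continue
                    m = models.make_model_for_grid_point(
                        self.model_family, self.seed, point
                    )
                    m.fit(Xf.loc[~test].to_numpy(), y[~test])
                    pred = m.predict(Xf.loc[test].to_numpy())
                    sq.append((pred - y[test]) ** 2)
                rmse = float(np.sqrt(np.mean(np.concatenate(sq))))
                if rmse < best_rmse:
                    best_point, best_rmse = point, rmse
            self.best_params_ = best_point
        else:
            self.best_params_ = points[0]

        self.model_ = models.make_model_for_grid_point(
            self.model_family, self.seed, self.best_params_
        )
        self.model_.fit(Xf.to_numpy(), y)
        self.feature_names_ = list(Xf.columns)
        self.n_features_in_ = len(self.feature_names_)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xf = self._as_frame(X, self.feature_names_)
        missing = [c for c in self.feature_names_ if c not in Xf.columns]
        if missing:
            raise KeyError(f"prediction rows missing feature columns: {missing}")
        pred = np.asarray(
            self.model_.predict(Xf[self.feature_names_].to_numpy()), dtype=float
        )
        if self.clip_cm is not None:
            pred = np.clip(pred, *self.clip_cm)
        return pred


@dataclass
class TrainedEstimator:
    """One fitted fold of the cross-validated pipeline."""

    model_family: str
    selected_features: list[str]
    hyper_parameters: dict
    fold_id: int
    training_subjects: set = field(default_factory=set)
    regressor: Optional[StepLengthRegressor] = None
    seed: int = 0


def fit_cv(
    matrix: pd.DataFrame,
    model_family: str = "gbt",
    selected_features: Optional[Sequence[str]] = None,
    n_folds: int = 5,
    seed: int = 0,
    hyper_grid: Optional[dict] = None,
    group_labels: Optional[dict] = None,
    clip_cm: Optional[tuple] = PREDICTION_CLIP_CM,
) -> pd.DataFrame:
    """Subject-wise cross-validated fit/predict over a feature matrix.

    Every subject is predicted exactly once, by the fold in which it was held
    out.  Returns the matrix's metadata plus ``predicted_cm`` and ``fold``.
    Raises if any fold has fewer than 2 training subjects.
    """
    matrix = matrix.reset_index(drop=True)
    feats = list(selected_features) if selected_features else feature_columns(matrix)
    subjects = matrix["subject_id"].to_numpy()
    y = matrix["target_cm"].to_numpy()
    fold_of = grouped_cv_split(
        subjects.tolist(), k=n_folds, seed=seed, group_labels=group_labels
    )

    out = matrix[[c for c in matrix.columns if c not in feats]].copy()
    out["predicted_cm"] = np.nan
    out["fold"] = -1
    for f in range(n_folds):
        test = np.array([fold_of[s] == f for s in subjects])
        train_subjects = {s for s in subjects[~test]}
        test_subjects = {s for s in subjects[test]}
        check_no_leakage(train_subjects, test_subjects)
        if len(train_subjects) < 2:
            raise ValueError(f"fold {f} has fewer than 2 training subjects")
        reg = StepLengthRegressor(
            model_family=model_family, hyper_grid=hyper_grid, seed=seed, clip_cm=clip_cm
        )
        reg.fit(matrix.loc[~test, feats], y[~test], groups=subjects[~test])
        out.loc[test, "predicted_cm"] = reg.predict(matrix.loc[test, feats])
        out.loc[test, "fold"] = f
    return out


def chord_step_length(
    pendulum_length_m: float, excursion_m: float, correction_factor: float = 1.0
) -> tuple[float, bool]:
    """Inverted-pendulum chord relation, in cm.

    Returns ``(length_cm, saturated)``; when h >= l the geometry degenerates
    and the geometric maximum 2*l is returned with the flag set.
    """
    l = pendulum_length_m
    h = excursion_m
    if l <= 0:
        raise ValueError("pendulum length must be positive")
    if correction_factor <= 0:
        raise ValueError("correction_factor must be positive")
    if h <= 0:
        return 0.0, False
    if h >= l:
        return correction_factor * 2.0 * l * 100.0, True
    return correction_factor * 2.0 * np.sqrt(2.0 * l * h - h * h) * 100.0, False


class InvertedPendulumEstimator(BaseEstimator):
    """Biomechanical baseline: step length from vertical CoM excursion.

    For each step the gravity-removed vertical acceleration is doubly
    integrated (endpoint-anchored velocity detrend); h is the peak-to-peak
    vertical displacement, and the chord relation gives the step length.
    """

    def __init__(self, pendulum_length_m: float = 0.88, correction_factor: float = 1.0):
        self.pendulum_length_m = pendulum_length_m
        self.correction_factor = correction_factor

    def estimate_step(
        self, rec: FilteredRecording, start_s: float, end_s: float
    ) -> float:
        if not getattr(rec, "gravity_removed", False):
            raise ValueError("pendulum estimation requires a gravity-removed recording")
        _, _, disp = integrate_window(
            rec.t, rec.vertical, start_s, end_s, detrend_velocity=True
        )
        h = float(disp.max() - disp.min())
        length_cm, _ = chord_step_length(
            self.pendulum_length_m, h, self.correction_factor
        )
        return length_cm

    def estimate_bout(self, rec: FilteredRecording, steps: StepTable) -> np.ndarray:
        return np.array(
            [
                self.estimate_step(rec, float(s["start_s"]), float(s["end_s"]))
                for _, s in steps.df.iterrows()
            ]
        )


def pendulum_estimate(
    rec: FilteredRecording,
    steps: StepTable,
    pendulum_length_m: float,
    correction_factor: float = 1.0,
) -> np.ndarray:
    """Functional wrapper over :class:`InvertedPendulumEstimator`."""
    est = InvertedPendulumEstimator(pendulum_length_m, correction_factor)
    return est.estimate_bout(rec, steps)


def average_estimates(
    pairs: pd.DataFrame, n: int, bout_cols: Sequence[str] = ("subject_id", "condition", "bout_id")
) -> pd.DataFrame:
    """Average estimate/reference pairs over consecutive non-overlapping blocks.

    Within each bout, consecutive blocks of ``n`` steps are averaged (both the
    estimate and the reference); a trailing remainder shorter than ``n`` is
    dropped.  ``n = 1`` is the identity.  Expects columns ``estimated_cm`` and
    ``reference_cm`` (plus the bout keys).
    """
    if n < 1:
        raise ValueError("averaging level n must be >= 1")
    cols = [c for c in bout_cols if c in pairs.columns]
    out_rows = []
    grouped = pairs.groupby(cols, sort=False) if cols else [((), pairs)]
    for key, bout in grouped:
        bout = bout.sort_values("start_s") if "start_s" in bout.columns else bout
        est = bout["estimated_cm"].to_numpy()
        ref = bout["reference_cm"].to_numpy()
        n_blocks = len(bout) // n
        for b in range(n_blocks):
            sl = slice(b * n, (b + 1) * n)
            row = {c: v for c, v in zip(cols, key if isinstance(key, tuple) else (key,))}
            for extra in ("group", "fold"):
                if extra in bout.columns:
                    row[extra] = bout[extra].iloc[b * n]
            row.update(
                block=b,
                n=n,
                estimated_cm=float(est[sl].mean()),
                reference_cm=float(ref[sl].mean()),
            )
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def gait_speed(length_cm: float, duration_s: float) -> float:
    """Gait speed (cm/s) from a step length and its duration."""
    if duration_s <= 0:
        raise ValueError("step duration must be positive")
    return length_cm / duration_s


def window_speed(distance_cm: float, window_s: float) -> float:
    """Gait speed (cm/s) from a window's traveled distance and its length."""
    if window_s <= 0:
        raise ValueError("window length must be positive")
    return distance_cm / window_s


def mcid_from_speed(speed_mcid_cm_s: float, step_duration_s: float) -> float:
    """Translate a gait-speed MCID into a step-length MCID (cm).

    A clinically meaningful gait-speed change of ``speed_mcid_cm_s`` sustained
    over steps of duration ``step_duration_s`` corresponds to a per-step
    length change of their product; e.g. 10 cm/s at ~0.5 s steps gives 5 cm.
    """
    if speed_mcid_cm_s < 0 or step_duration_s < 0:
        raise ValueError("inputs must be non-negative")
    return speed_mcid_cm_s * step_duration_s
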