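"""End-to-end orchestration: simulate -> preprocess -> segment -> featurize ->
select -> train -> evaluate, with the pendulum and mean-predictor baselines.

This is the programmatic spine used by the CLI and by reproduction scripts;
each stage is importable on its own from its module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import estimation, features, preprocessing, segmentation
from .evaluation import AgreementReport, build_report, rmse
from .io import PipelineConfig
from .synthetic import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    pairs: pd.DataFrame  # per-step estimate/reference pairs with fold labels
    report: AgreementReport
    baseline_rmse_mean_predictor: float
    baseline_rmse_pendulum: Optional[float]
    model_rmse: float
    selected_features: list[str]
    matched_fraction: float  # detected steps matched to ground truth


def default_study_cohort(
    seed: int,
    subjects_per_group: int = 20,
    n_steps_per_bout: int = 12,
    noise_sd: float = 0.3,
    conditions: tuple = ("usual", "fast", "dual-task"),
) -> CohortSpec:
    """The canonical synthetic study cohort: three clinical-like groups
    (older adults, Parkinson-like, MCI-like), realistic sensor noise, and the
    three walking conditions."""
    from .synthetic import DEFAULT_GROUP_PARAMS, GroupSpec

    groups = [
        GroupSpec(group=g, n_subjects=subjects_per_group, noise_sd=noise_sd,
                  **DEFAULT_GROUP_PARAMS[g])
        for g in ("OA-like", "PD-like", "MCI-like")
    ]
    return CohortSpec(
        groups=groups,
        conditions=conditions,
        n_steps_per_bout=n_steps_per_bout,
        seed=seed,
    )


def featurize_cohort(
    cohort: dict,
    config: PipelineConfig,
    use_detected_steps: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Preprocess, segment, synchronize, and featurize every bout.

    Returns the step feature matrix, the per-bout pendulum estimates paired
    with references, and the fraction of reference steps recovered by
    segmentation and matching.
    """
    matrices = []
    pendulum_rows = []
    n_ref = 0
    n_matched = 0
    for (subject_id, condition, bout_id), (rec, truth) in cohort.items():
        conditioned = preprocessing.preprocess(rec, config.filter_cutoff)
        if use_detected_steps:
            detected = segmentation.segment_steps(conditioned)
            steps = segmentation.attach_reference_lengths(detected, truth)
        else:
            steps = truth
        n_ref += len(truth)
        n_matched += len(steps)
        if len(steps) == 0:
            logger.warning(
                "no steps recovered for %s/%s/%s", subject_id, condition, bout_id
            )
            continue
        matrices.append(features.build_step_feature_matrix(conditioned, steps))

        # calibration-free baseline: a population pendulum length, not the
        # subject's true leg length (heights are not measured)
        pend = estimation.pendulum_estimate(
            conditioned, steps, config.pendulum_length_m
        )
        pendulum_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "group": steps.df.get("group", rec.group),
                    "condition": condition,
                    "bout_id": bout_id,
                    "start_s": steps.df["start_s"].to_numpy(),
                    "estimated_cm": estimation.clip_predictions(pend),
                    "reference_cm": steps.df["reference_length_cm"].to_numpy(),
                }
            )
        )
    if not matrices:
        raise ValueError("no bout produced any usable steps")
    matrix = pd.concat(matrices, ignore_index=True)
    pendulum_pairs = pd.concat(pendulum_rows, ignore_index=True)
    matched_fraction = n_matched / n_ref if n_ref else 0.0
    return matrix, pendulum_pairs, matched_fraction


def run_pipeline(
    spec: CohortSpec,
    config: Optional[PipelineConfig] = None,
    use_detected_steps: bool = True,
) -> PipelineResult:
    """Simulate a cohort and run the full estimation + evaluation chain."""
    config = config or PipelineConfig(seed=spec.seed)
    cohort = simulate_cohort(spec)
    matrix, pendulum_pairs, matched_fraction = featurize_cohort(
        cohort, config, use_detected_steps
    )
    group_of = dict(zip(matrix["subject_id"], matrix["group"]))

    selected = features.stepwise_select(
        matrix,
        model_family=config.selection_model_family,
        max_features=config.max_features,
        n_folds=config.n_folds,
        seed=config.seed,
    )
    logger.info("selected %d features: %s", len(selected), selected)

    cv = estimation.fit_cv(
        matrix,
        model_family=config.model_family,
        selected_features=selected,
        n_folds=config.n_folds,
        seed=config.seed,
        group_labels=group_of,
    )
    pairs = cv.rename(columns={"predicted_cm": "estimated_cm", "target_cm": "reference_cm"})
    pairs = pairs[
        [
            c
            for c in (
                "subject_id",
                "group",
                "condition",
                "bout_id",
                "step_index",
                "start_s",
                "duration_s",
                "estimated_cm",
                "reference_cm",
                "fold",
            )
            if c in pairs.columns
        ]
    ]

    report = build_report(pairs, averaging_levels=config.averaging_levels)

    ref = pairs["reference_cm"].to_numpy()
    est = pairs["estimated_cm"].to_numpy()
    model_rmse = rmse(est, ref)

    # mean-predictor baseline, honoring the same folds (train-fold mean)
    fold_means = {
        f: pairs.loc[pairs["fold"] != f, "reference_cm"].mean()
        for f in pairs["fold"].unique()
    }
    mean_pred = np.array([fold_means[f] for f in pairs["fold"]])
    baseline_mean = rmse(mean_pred, ref)

    baseline_pendulum = rmse(
        pendulum_pairs["estimated_cm"], pendulum_pairs["reference_cm"]
    )

    return PipelineResult(
        pairs=pairs,
        report=report,
        baseline_rmse_mean_predictor=baseline_mean,
        baseline_rmse_pendulum=baseline_pendulum,
        model_rmse=model_rmse,
        selected_features=selected,
        matched_fraction=matched_fraction,
    )


def step_model_speed_rmse(pairs: pd.DataFrame) -> float:
    """Gait-speed RMSE (cm/s) of the step model: length / step duration."""
    dur = pairs["duration_s"].to_numpy()
    est = pairs["estimated_cm"].to_numpy() / dur
    ref = pairs["reference_cm"].to_numpy() / dur
    return rmse(est, ref)


def run_window_model(
    spec: CohortSpec,
    window_length_s: float,
    config: Optional[PipelineConfig] = None,
    windows_per_bout: int = 8,
) -> float:
    """Non-segmented variant: gait-speed RMSE (cm/s) of a fixed-window model.

    The model is trained on seeded random fixed-duration windows (target:
    reference distance traveled in the window); speed is the predicted
    distance over the window length.  No step segmentation is needed.
    """
    config = config or PipelineConfig(seed=spec.seed)
    cohort = simulate_cohort(spec)
    matrices = []
    for i, ((subject_id, condition, bout_id), (rec, truth)) in enumerate(cohort.items()):
        conditioned = preprocessing.preprocess(rec, config.filter_cutoff)
        matrices.append(
            features.extract_window_features(
                conditioned,
                truth,
                window_length_s,
                n_windows=windows_per_bout,
                seed=config.seed + i,
            )
        )
    matrix = pd.concat(matrices, ignore_index=True)
    cv = estimation.fit_cv(
        matrix,
        model_family=config.model_family,
        n_folds=config.n_folds,
        seed=config.seed,
        clip_cm=None,  # window targets are distances, not step lengths
    )
    est_speed = cv["predicted_cm"].to_numpy() / window_length_s
    ref_speed = cv["target_cm"].to_numpy() / window_length_s
    return rmse(est_speed, ref_speed)
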