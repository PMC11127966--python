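"""Feature extraction oracles (constants, kinematics, DFT identities),
invariances, and the forward-selection oracle against exhaustive search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LinearRegression

from steplen import ForwardStepwiseSelector, StepTable, stepwise_select
from steplen.features import (
    build_step_feature_matrix,
    extract_segment_features,
    extract_window_features,
    feature_columns,
    window_target_cm,
)
from steplen.validation import grouped_cv_split


def _acc(y, x=None, z=None):
    n = len(y)
    x = np.zeros(n) if x is None else x
    z = np.zeros(n) if z is None else z
    return np.column_stack([x, y, z])


FS = 128.0


def test_zero_signal_features_vanish():
    t = np.arange(128) / FS
    feats = extract_segment_features(t, _acc(np.zeros(128)), 0.0, 0.9)
    assert feats["energy_mag"] == 0.0
    assert all(feats[f"fft_v_{k}"] == 0.0 for k in range(10))
    assert feats["disp_net_ml"] == 0.0 and feats["disp_net_v"] == 0.0


def test_fft_of_constant_is_the_mean():
    t = np.arange(256) / FS
    c = -2.5
    feats = extract_segment_features(t, _acc(np.full(256, c)), 0.0, 1.5)
    assert feats["fft_v_0"] == pytest.approx(c, abs=1e-12)
    assert all(abs(feats[f"fft_v_{k}"]) < 1e-12 for k in range(1, 10))


def test_constant_acceleration_displacement_kinematics():
    """a = 1 m/s^2 over T = 0.5 s gives d = a T^2 / 2 = 0.125 m (no detrend)."""
    t = np.arange(int(2 * FS)) / FS
    feats = extract_segment_features(
        t, _acc(np.ones(t.size)), 0.0, 0.5, detrend_velocity=False
    )
    assert feats["disp_net_v"] == pytest.approx(0.125, rel=1e-3)


def test_degenerate_step_rejected():
    t = np.arange(128) / FS
    with pytest.raises(ValueError):
        extract_segment_features(t, _acc(np.zeros(128)), 0.0, 0.015)


def test_translation_invariance_in_time():
    """Shifting a step by whole samples leaves every feature unchanged."""
    rng = np.random.default_rng(3)
    sig = rng.normal(size=256)
    t = np.arange(1024) / FS
    y = np.zeros(1024)
    shift = 128
    y[100 : 100 + 256] = sig
    f1 = extract_segment_features(t, _acc(y), 100 / FS, (100 + 256) / FS)
    y2 = np.zeros(1024)
    y2[100 + shift : 100 + shift + 256] = sig
    f2 = extract_segment_features(
        t, _acc(y2), (100 + shift) / FS, (100 + shift + 256) / FS
    )
    for key in f1:
        if key == "duration":
            continue
        assert f1[key] == pytest.approx(f2[key], abs=1e-9), key


@settings(deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0))
def test_energy_scales_quadratically(scale):
    rng = np.random.default_rng(11)
    y = rng.normal(size=200)
    t = np.arange(200) / FS
    base = extract_segment_features(t, _acc(y), 0.0, 1.5)["energy_mag"]
    scaled = extract_segment_features(t, _acc(scale * y), 0.0, 1.5)["energy_mag"]
    assert scaled == pytest.approx(scale**2 * base, rel=1e-9)
    assert scaled >= 0.0


def _ref_table(starts, ends, lengths):
    return StepTable(
        pd.DataFrame(
            {
                "step_index": np.arange(len(starts)),
                "start_s": starts,
                "end_s": ends,
                "reference_length_cm": lengths,
            }
        )
    )


def test_window_target_exact_cover_and_prorating():
    starts = np.arange(10) * 0.5
    ref = _ref_table(starts, starts + 0.5, np.full(10, 60.0))
    # 1 s window exactly covering steps 3 and 4 (0-based rows 2 and 3)
    assert window_target_cm(ref, 1.0, 2.0) == pytest.approx(120.0)
    # window half-overlapping one step contributes half its length
    assert window_target_cm(ref, 0.25, 0.5) == pytest.approx(30.0)


def test_window_features_deterministic_and_bounded(noiseless_conditioned):
    rec, truth = noiseless_conditioned
    m1 = extract_window_features(rec, truth, 1.0, n_windows=5, seed=9)
    m2 = extract_window_features(rec, truth, 1.0, n_windows=5, seed=9)
    pd.testing.assert_frame_equal(m1, m2)
    assert (m1["start_s"] >= truth.df["start_s"].min()).all()
    with pytest.raises(ValueError):
        extract_window_features(rec, truth, 1000.0, n_windows=2, seed=0)


def _toy_matrix(n=120, n_subjects=6, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = X[:, 0] * 10 + 55 if informative else rng.normal(size=n) + 55
    df = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
    df["target_cm"] = y
    df["subject_id"] = [f"s{i % n_subjects}" for i in range(n)]
    return df


def test_perfect_predictor_selected_first():
    df = _toy_matrix()
    # add noise features that cannot help
    selected = stepwise_select(df, model_family="lr", max_features=2, seed=1)
    assert selected[0] == "x1"


def test_selection_matches_exhaustive_pair_search():
    """Greedy forward selection of 2 features equals brute-force search over
    all pairs on a toy problem where greedy is optimal."""
    rng = np.random.default_rng(5)
    n = 150
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "x3": rng.normal(size=n),
            "x4": rng.normal(size=n),
        }
    )
    df["target_cm"] = 8 * x1 + 3 * x2 + rng.normal(0, 0.5, size=n) + 55
    df["subject_id"] = [f"s{i % 5}" for i in range(n)]

    greedy = stepwise_select(df, model_family="lr", max_features=2, seed=2)

    # brute-force oracle: same folds, exhaustive over pairs
    fold_of = grouped_cv_split(df["subject_id"].tolist(), k=5, seed=2)
    feats = ["x1", "x2", "x3", "x4"]

    def cv_rmse(cols):
        sq = []
        for f in range(5):
            test = df["subject_id"].map(fold_of) == f
            m = LinearRegression().fit(df.loc[~test, cols], df.loc[~test, "target_cm"])
            pred = m.predict(df.loc[test, cols])
            sq.append((pred - df.loc[test, "target_cm"].to_numpy()) ** 2)
        return np.sqrt(np.mean(np.concatenate(sq)))

    best_pair = min(itertools.combinations(feats, 2), key=cv_rmse)
    assert set(greedy) == set(best_pair)


def test_selecting_all_informative_features_is_a_permutation():
    rng = np.random.default_rng(8)
    n = 200
    X = rng.normal(size=(n, 4))
    df = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
    df["target_cm"] = X @ np.array([5.0, 4.0, 3.0, 2.0]) + 60
    df["subject_id"] = [f"s{i % 5}" for i in range(n)]
    selected = stepwise_select(df, model_family="lr", max_features=4, seed=3)
    assert sorted(selected) == ["x1", "x2", "x3", "x4"]


def test_selection_rmse_path_non_increasing():
    df = _toy_matrix(seed=7)
    sel = ForwardStepwiseSelector(model_family="lr", max_features=4, seed=4).fit(df)
    path = np.array(sel.rmse_path_)
    assert np.all(np.diff(path) <= 1e-12)


def test_non_finite_features_rejected():
    df = _toy_matrix()
    df.loc[0, "x2"] = np.nan
    with pytest.raises(ValueError):
        stepwise_select(df, model_family="lr", max_features=2, seed=0)


def test_step_feature_matrix_shape_and_finiteness(noiseless_conditioned):
    rec, truth = noiseless_conditioned
    matrix = build_step_feature_matrix(rec, truth)
    assert len(matrix) == len(truth)
    cols = feature_columns(matrix)
    assert len(cols) >= 40  # documented superset of the named families
    assert np.all(np.isfinite(matrix[cols].to_numpy()))
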