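"""Regression-core contracts, the pendulum chord formula, n-step averaging,
and gait-speed arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steplen import (
    InvertedPendulumEstimator,
    StepLengthRegressor,
    average_estimates,
    chord_step_length,
    gait_speed,
    mcid_from_speed,
    pendulum_estimate,
    window_speed,
)
from steplen.estimation import fit_cv


def _matrix(n=100, n_subjects=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    df["target_cm"] = 2.0 * X[:, 0] + 3.0 + 55.0
    df["subject_id"] = [f"s{i % n_subjects}" for i in range(n)]
    return df


def test_knn_k1_memorizes_training_rows():
    df = _matrix()
    reg = StepLengthRegressor("knn", hyper_grid={"n_neighbors": [1]}, seed=0)
    reg.fit(df[["x1", "x2", "x3"]], df["target_cm"], groups=df["subject_id"])
    pred = reg.predict(df[["x1", "x2", "x3"]])
    assert np.allclose(pred, df["target_cm"], atol=1e-9)


def test_linear_regression_recovers_exact_coefficients():
    df = _matrix()
    reg = StepLengthRegressor("lr", seed=0)
    reg.fit(df[["x1"]], df["target_cm"])
    lr = reg.model_
    assert lr.coef_[0] == pytest.approx(2.0, abs=1e-6)
    assert lr.intercept_ == pytest.approx(58.0, abs=1e-6)
    assert np.sqrt(np.mean((reg.predict(df[["x1"]]) - df["target_cm"]) ** 2)) < 1e-6


def test_predictions_respect_clip_envelope():
    df = _matrix()
    df["target_cm"] = 1000.0  # force absurd targets
    reg = StepLengthRegressor("lr", seed=0)
    reg.fit(df[["x1"]], df["target_cm"])
    pred = reg.predict(df[["x1"]])
    assert np.all((pred >= 5.0) & (pred <= 150.0))


def test_prediction_missing_feature_errors():
    df = _matrix()
    reg = StepLengthRegressor("lr", seed=0)
    reg.fit(df[["x1", "x2"]], df["target_cm"])
    with pytest.raises(KeyError):
        reg.predict(df[["x1"]])


def test_permuting_rows_permutes_predictions():
    df = _matrix()
    reg = StepLengthRegressor("lr", seed=0)
    reg.fit(df[["x1", "x2"]], df["target_cm"])
    perm = np.random.default_rng(1).permutation(len(df))
    p_all = reg.predict(df[["x1", "x2"]])
    p_perm = reg.predict(df[["x1", "x2"]].iloc[perm])
    assert np.allclose(p_perm, p_all[perm])


def test_fit_cv_requires_enough_subjects():
    df = _matrix(n_subjects=3)
    with pytest.raises(ValueError):
        fit_cv(df, model_family="lr", n_folds=5, seed=0)


def test_chord_formula_closed_form():
    """l = 1 m, h from the 60 cm inverse: the chord returns 60.0 cm."""
    l = 1.0
    h = l - np.sqrt(l**2 - 0.3**2)
    length, flag = chord_step_length(l, h)
    assert length == pytest.approx(60.0, abs=0.01)
    assert not flag
    assert chord_step_length(l, 0.0) == (0.0, False)


def test_chord_saturates_at_geometric_maximum():
    length, flag = chord_step_length(0.9, 1.2)
    assert flag
    assert length == pytest.approx(180.0)
    with pytest.raises(ValueError):
        chord_step_length(-1.0, 0.05)


@settings(deadline=None, derandomize=True)
@given(st.floats(0.001, 0.899), st.floats(0.001, 0.899))
def test_chord_strictly_monotone_in_excursion(h1, h2):
    l = 0.9
    if h1 == h2:
        return
    lo, hi = sorted((h1, h2))
    s_lo, _ = chord_step_length(l, lo)
    s_hi, _ = chord_step_length(l, hi)
    assert s_hi > s_lo


def test_pendulum_recovers_noiseless_steps(noiseless_conditioned, noiseless_subject):
    rec, truth = noiseless_conditioned
    est = pendulum_estimate(rec, truth, noiseless_subject.pendulum_length)
    assert np.abs(est - truth.reference_lengths).max() < 1.0


def test_pendulum_requires_gravity_removed(noiseless_bout):
    rec, truth = noiseless_bout
    with pytest.raises(ValueError):
        InvertedPendulumEstimator(0.88).estimate_bout(rec, truth)


def _pairs(estimates, references, starts=None):
    n = len(estimates)
    return pd.DataFrame(
        {
            "subject_id": "s",
            "condition": "usual",
            "bout_id": "0",
            "start_s": starts if starts is not None else np.arange(n, dtype=float),
            "estimated_cm": estimates,
            "reference_cm": references,
        }
    )


def test_averaging_mean_of_block():
    out = average_estimates(_pairs([50.0, 60.0, 70.0], [55.0, 60.0, 65.0]), n=3)
    assert len(out) == 1
    assert out["estimated_cm"].iloc[0] == pytest.approx(60.0)
    assert out["reference_cm"].iloc[0] == pytest.approx(60.0)


def test_averaging_drops_trailing_remainder():
    out = average_estimates(_pairs(np.arange(7.0), np.arange(7.0)), n=3)
    assert len(out) == 2


def test_averaging_identity_at_n1():
    pairs = _pairs([50.0, 60.0, 70.0], [55.0, 62.0, 66.0])
    out = average_estimates(pairs, n=1)
    assert np.allclose(out["estimated_cm"], pairs["estimated_cm"])
    assert np.allclose(out["reference_cm"], pairs["reference_cm"])
    with pytest.raises(ValueError):
        average_estimates(pairs, n=0)


def test_averaging_never_crosses_bout_boundaries():
    a = _pairs(np.full(4, 50.0), np.full(4, 50.0))
    b = _pairs(np.full(4, 90.0), np.full(4, 90.0))
    b["bout_id"] = "1"
    out = average_estimates(pd.concat([a, b], ignore_index=True), n=3)
    assert len(out) == 2  # one block per bout; remainders never merge
    assert set(out["estimated_cm"]) == {50.0, 90.0}


def test_averaging_error_contraction_rate():
    """iid noise of sd sigma contracts as sigma/sqrt(n) under n-block averaging."""
    rng = np.random.default_rng(21)
    sigma = 6.0
    n_steps = 30000
    ref = rng.uniform(40, 80, size=n_steps)
    est = ref + rng.normal(0, sigma, size=n_steps)
    pairs = _pairs(est, ref)
    rmse_by_n = {}
    for n in (1, 3, 5, 10):
        out = average_estimates(pairs, n=n)
        assert len(out) >= 2000
        rmse_by_n[n] = float(
            np.sqrt(np.mean((out["estimated_cm"] - out["reference_cm"]) ** 2))
        )
        assert rmse_by_n[n] == pytest.approx(sigma / np.sqrt(n), rel=0.10)
    assert rmse_by_n[10] < rmse_by_n[5] < rmse_by_n[3] < rmse_by_n[1]


def test_gait_speed_arithmetic():
    assert gait_speed(60.0, 0.5) == pytest.approx(120.0)
    assert gait_speed(0.0, 0.7) == 0.0
    assert window_speed(500.0, 5.0) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        gait_speed(60.0, 0.0)
    with pytest.raises(ValueError):
        window_speed(100.0, -1.0)


def test_mcid_conversion():
    """A 10 cm/s gait-speed MCID over ~0.5 s steps is a 5 cm length MCID."""
    assert mcid_from_speed(10.0, 0.5) == pytest.approx(5.0)
    assert mcid_from_speed(20.0, 0.5) == pytest.approx(10.0)
    assert mcid_from_speed(0.0, 0.5) == 0.0
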