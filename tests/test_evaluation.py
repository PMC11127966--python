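"""Agreement-statistic oracles: hand-computed ANOVA decompositions, an
independent ICC implementation (pingouin), Bland-Altman arithmetic, and the
cross-validation partition contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steplen import (
    anova_averaging,
    bland_altman,
    build_report,
    correlation,
    grouped_cv_split,
    icc_2_1,
    icc_label,
    ra,
    rmse,
)


def test_rmse_and_ra_exact_cases():
    ref = np.array([50.0, 60.0])
    assert rmse(ref, ref) == 0.0
    assert ra(ref, ref) == 0.0
    # errors {3, 4} cm -> sqrt(12.5)
    assert rmse(ref + [3.0, 4.0], ref) == pytest.approx(np.sqrt(12.5))
    assert ra(1.1 * ref, ref) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        rmse([], [])


def test_rmse_decomposes_into_bias_and_variance(rng):
    est = rng.normal(60, 5, size=500)
    ref = rng.normal(60, 5, size=500)
    err = est - ref
    assert rmse(est, ref) ** 2 == pytest.approx(
        err.mean() ** 2 + err.var(ddof=0), rel=1e-12
    )


def test_icc_perfect_agreement_is_one():
    x = np.array([50.0, 60.0, 70.0])
    assert icc_2_1(x, x) == pytest.approx(1.0)


def test_icc_offset_fixture_matches_hand_decomposition():
    """ref = [50, 60, 70], est = ref + 2: the two-way decomposition gives
    SSrows = 400, SScols = 6, SSerr = 0, so ICC = 200 / 204."""
    ref = np.array([50.0, 60.0, 70.0])
    val = icc_2_1(ref + 2.0, ref)
    assert val == pytest.approx(200.0 / 204.0, abs=1e-12)
    assert 0.9 < val < 1.0


def test_icc_agrees_with_independent_implementation(rng):
    pingouin = pytest.importorskip("pingouin")
    ref = rng.uniform(40, 80, size=60)
    est = ref + rng.normal(0, 5, size=60)
    ours = icc_2_1(est, ref)
    data = pd.DataFrame(
        {
            "targets": np.tile(np.arange(60), 2),
            "raters": ["est"] * 60 + ["ref"] * 60,
            "score": np.concatenate([est, ref]),
        }
    )
    theirs = pingouin.intraclass_corr(
        data, targets="targets", raters="raters", ratings="score"
    )
    # two-way random effects, absolute agreement, single measure
    mask = theirs["Type"].isin(["ICC2", "ICC(A,1)"])
    icc2 = theirs.loc[mask, "ICC"].iloc[0]
    assert ours == pytest.approx(icc2, abs=1e-9)


def test_icc_of_shuffled_pairs_is_near_zero(rng):
    ref = rng.uniform(40, 80, size=4000)
    est = rng.permutation(ref)
    assert abs(icc_2_1(est, ref)) < 0.05


def test_icc_undefined_on_zero_variance():
    x = np.full(5, 60.0)
    assert icc_2_1(x, x) is None


def test_icc_reliability_bands_at_boundaries():
    assert icc_label(0.49) == "poor"
    assert icc_label(0.5) == "moderate"
    assert icc_label(0.75) == "moderate"
    assert icc_label(0.76) == "good"
    assert icc_label(0.9) == "good"
    assert icc_label(0.91) == "excellent"


def test_bland_altman_hand_arithmetic():
    ref = np.zeros(3)
    out = bland_altman(ref + [2.0, 2.0, 2.0], ref)
    assert out["mean_diff"] == pytest.approx(2.0)
    assert out["loa_lower"] == pytest.approx(2.0)
    assert out["loa_upper"] == pytest.approx(2.0)

    out = bland_altman(ref + [1.0, 2.0, 3.0], ref)  # sd = 1
    assert out["mean_diff"] == pytest.approx(2.0)
    assert out["loa_lower"] == pytest.approx(0.04)
    assert out["loa_upper"] == pytest.approx(3.96)
    assert out["loa_upper"] - out["loa_lower"] == pytest.approx(3.92 * out["sd_diff"])


def test_bland_altman_negation_symmetry(rng):
    ref = rng.uniform(40, 80, size=30)
    est = ref + rng.normal(0, 4, size=30)
    fwd = bland_altman(est, ref)
    rev = bland_altman(2 * ref - est, ref)  # negated differences
    assert rev["mean_diff"] == pytest.approx(-fwd["mean_diff"])
    assert rev["loa_lower"] == pytest.approx(-fwd["loa_upper"])
    assert rev["loa_upper"] == pytest.approx(-fwd["loa_lower"])


def test_correlation_affine_and_degenerate_cases(rng):
    ref = np.array([50.0, 60.0, 70.0, 80.0])
    assert correlation(2 * ref + 1, ref)["pearson_r"] == pytest.approx(1.0)
    assert correlation(-ref, ref)["pearson_r"] == pytest.approx(-1.0)
    n = 5000
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    assert abs(correlation(a + 60, b + 60)["pearson_r"]) < 3 / np.sqrt(n)
    assert correlation(np.full(4, 60.0), ref)["pearson_r"] is None


def test_identity_line_r2_penalizes_bias(rng):
    ref = rng.uniform(40, 80, size=200)
    out = correlation(ref + 10.0, ref)  # perfectly correlated but biased
    assert out["pearson_r"] == pytest.approx(1.0)
    assert out["r2"] < 1.0


def test_anova_identical_groups_f_zero():
    f, p = anova_averaging({1: [5.0, 5.0], 3: [5.0, 5.0], 5: [5.0, 5.0]})
    assert f == 0.0
    assert p == 1.0


def test_anova_degenerate_within_variance_flags_infinite_f():
    f, p = anova_averaging({1: [0.0, 0.0], 2: [1.0, 1.0]})
    assert np.isinf(f)
    assert p == 0.0


def test_anova_matches_scipy_on_crafted_table(rng):
    groups = {n: rng.normal(6.0 - 0.1 * n, 0.4, size=5).tolist() for n in (1, 3, 5, 10)}
    f_ours, p_ours = anova_averaging(groups)
    f_ref, p_ref = stats.f_oneway(*groups.values())
    assert f_ours == pytest.approx(float(f_ref), rel=1e-12)
    assert p_ours == pytest.approx(float(p_ref), rel=1e-9)


def test_grouped_split_partition_properties():
    subjects = [f"s{i}" for i in range(10)]
    fold_of = grouped_cv_split(subjects, k=5, seed=3)
    assert set(fold_of) == set(subjects)
    sizes = pd.Series(list(fold_of.values())).value_counts()
    assert sorted(sizes) == [2, 2, 2, 2, 2]
    assert grouped_cv_split(subjects, k=5, seed=3) == fold_of  # deterministic
    with pytest.raises(ValueError):
        grouped_cv_split(subjects, k=11, seed=0)


def test_grouped_split_stratifies_by_group():
    subjects = [f"s{i}" for i in range(12)]
    labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(subjects)}
    fold_of = grouped_cv_split(subjects, k=3, seed=1, group_labels=labels)
    for f in range(3):
        members = [s for s, ff in fold_of.items() if ff == f]
        assert {labels[s] for s in members} == {"A", "B"}


def _pairs_frame(rng, n_per_group=40):
    rows = []
    for g in ("OA-like", "PD-like", "MCI-like"):
        ref = rng.uniform(45, 75, size=n_per_group)
        est = ref + rng.normal(0, 4, size=n_per_group)
        for i, (e, r) in enumerate(zip(est, ref)):
            rows.append(
                dict(
                    subject_id=f"{g}-{i % 4}",
                    group=g,
                    condition="usual",
                    bout_id="0",
                    start_s=float(i),
                    estimated_cm=e,
                    reference_cm=r,
                    fold=i % 5,
                )
            )
    return pd.DataFrame(rows)


def test_report_perfect_predictions(rng):
    pairs = _pairs_frame(rng)
    pairs["estimated_cm"] = pairs["reference_cm"]
    rep = build_report(pairs, averaging_levels=(1, 3))
    assert rep.overall["rmse"] == 0.0
    assert rep.overall["icc_2_1"] == pytest.approx(1.0)
    for stratum in rep.by_group.values():
        assert stratum["rmse"] == 0.0


def test_report_strata_additivity(rng):
    pairs = _pairs_frame(rng)
    rep = build_report(pairs, averaging_levels=(1, 3, 5))
    assert rep.overall["n_pairs"] == sum(
        m["n_pairs"] for m in rep.by_group.values()
    )
    assert set(rep.by_group) == {"OA-like", "PD-like", "MCI-like"}
    assert rep.anova is not None


def test_single_group_report_equals_overall(rng):
    pairs = _pairs_frame(rng)
    pairs = pairs[pairs["group"] == "OA-like"].reset_index(drop=True)
    rep = build_report(pairs, averaging_levels=(1,))
    assert list(rep.by_group) == ["OA-like"]
    assert rep.by_group["OA-like"]["rmse"] == pytest.approx(rep.overall["rmse"])
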