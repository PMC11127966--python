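"""Agreement statistics between estimated and reference step lengths.

Implements the full validation protocol used for wearable-vs-walkway
comparisons: RMSE, relative error (RA), ICC(2,1) (two-way random effects,
absolute agreement, single measure), Bland-Altman 95% limits of agreement,
Pearson correlation with identity-line R^2, and a one-way ANOVA across
n-step averaging levels, plus stratified report assembly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .validation import grouped_cv_split  # noqa: F401  (re-export: protocol surface)

logger = logging.getLogger(__name__)

def _pairs(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference must have the same shape")
    if est.size == 0:
        raise ValueError("need at least one estimate/reference pair")
    return est, ref


def rmse(est, ref) -> float:
    """Root mean square error, same units as the inputs."""
    est, ref = _pairs(est, ref)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def ra(est, ref) -> float:
    """Relative error in %: mean absolute error relative to the reference."""
    est, ref = _pairs(est, ref)
    if np.any(ref <= 0):
        raise ValueError("relative error needs strictly positive references")
    return float(100.0 * np.mean(np.abs(est - ref) / ref))


def icc_2_1(est, ref) -> Optional[float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    With n targets (steps) rated by k = 2 raters (estimate, reference):

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))

    where MSR/MSC/MSE are the rows (targets), columns (raters), and residual
    mean squares of the two-way ANOVA decomposition.  Returns ``None`` when
    the total variance is zero and the coefficient is undefined.
    """
    est, ref = _pairs(est, ref)
    n = est.size
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    k = 2
    data = np.column_stack([est, ref])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_total = float(((data - grand) ** 2).sum())
    if ss_total == 0.0:
        return None
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return None
    return float((msr - mse) / denom)


def icc_label(icc: float) -> str:
    """Reliability band of an ICC point estimate.

    < 0.5 poor; [0.5, 0.75] moderate; (0.75, 0.9] good; > 0.9 excellent.
    """
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def bland_altman(est, ref) -> dict[str, float]:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 sd, ddof=1)."""
    est, ref = _pairs(est, ref)
    if est.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = est - ref
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_lower": mean_diff - 1.96 * sd,
        "loa_upper": mean_diff + 1.96 * sd,
        "sd_diff": sd,
    }


def correlation(est, ref) -> dict[str, Optional[float]]:
    """Pearson r of (est, ref) and the identity-line R^2.

    R^2 here measures agreement with the y = x line (1 - SSres/SStot with the
    estimate taken as the prediction of the reference), not the best-fit line.
    Returns ``None`` values when either input has zero variance.
    """
    est, ref = _pairs(est, ref)
    if est.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if est.std() == 0.0 or ref.std() == 0.0:
        return {"pearson_r": None, "r2": None}
    r = float(stats.pearsonr(est, ref).statistic)
    ss_res = float(((ref - est) ** 2).sum())
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return {"pearson_r": r, "r2": r2}


def anova_averaging(groups: Mapping[int, Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA of per-fold RMSE values across averaging levels.

    Returns ``(F, p)``; F is ``inf`` (p = 0) when the within-group variance is
    zero but the group means differ.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every ANOVA group needs at least 2 values")
    grand = np.concatenate(arrays).mean()
    n_total = sum(a.size for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = float(ms_between / ms_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return f, p


def agreement_metrics(est, ref) -> dict:
    """All pairwise agreement metrics for one stratum of pairs."""
    est, ref = _pairs(est, ref)
    out: dict = {"n_pairs": int(est.size), "rmse": rmse(est, ref)}
    out["ra"] = ra(est, ref) if np.all(ref > 0) else None
    out["icc_2_1"] = icc_2_1(est, ref) if est.size >= 3 else None
    if out["icc_2_1"] is not None:
        out["icc_band"] = icc_label(out["icc_2_1"])
    if est.size >= 2:
        out["bland_altman"] = bland_altman(est, ref)
    if est.size >= 3:
        out.update(correlation(est, ref))
    return out


def _per_fold(df: pd.DataFrame, metric) -> Optional[dict]:
    if "fold" not in df.columns or df["fold"].nunique() < 2:
        return None
    vals = [
        metric(sub["estimated_cm"].to_numpy(), sub["reference_cm"].to_numpy())
        for _, sub in df.groupby("fold")
        if len(sub) >= 2
    ]
    if not vals:
        return None
    vals = np.array(vals, dtype=float)
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)), "values": vals.tolist()}


@dataclass
class AgreementReport:
    """Stratified agreement results, serializable to JSON and Markdown."""

    overall: dict
    by_group: dict
    by_condition: dict
    by_averaging: dict
    anova: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "by_group": self.by_group,
            "by_condition": self.by_condition,
            "by_averaging": self.by_averaging,
            "anova": self.anova,
            "schema_version": 1,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Agreement report", "", "## Overall", ""]
        lines += _metrics_md(self.overall)
        for title, table in (
            ("By group", self.by_group),
            ("By condition", self.by_condition),
            ("By averaging level", self.by_averaging),
        ):
            if not table:
                continue
            lines += ["", f"## {title}", ""]
            for key, metrics in table.items():
                lines += [f"### {key}", ""]
                lines += _metrics_md(metrics)
        if self.anova:
            lines += [
                "",
                "## ANOVA across averaging levels",
                "",
                f"F = {self.anova['F']:.3f}, p = {self.anova['p']:.3g}",
            ]
        return "\n".join(lines) + "\n"


def _metrics_md(metrics: dict) -> list[str]:
    rows = ["| metric | value |", "|---|---|"]
    for key, val in metrics.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                if isinstance(v2, (int, float)):
                    rows.append(f"| {key}.{k2} | {v2:.4g} |")
        elif isinstance(val, (int, float)):
            rows.append(f"| {key} | {val:.4g} |")
        elif val is not None:
            rows.append(f"| {key} | {val} |")
    return rows


def build_report(
    pairs: pd.DataFrame,
    averaging_levels: Sequence[int] = (1, 3, 5, 10),
) -> AgreementReport:
    """Assemble the stratified agreement report.

    ``pairs`` carries one row per step with ``estimated_cm`` and
    ``reference_cm`` plus ``subject_id``/``group``/``condition``/``bout_id``
    labels and (optionally) a ``fold`` column for per-fold mean +/- sd.
    Strata with no pairs are omitted with a logged notice.
    """
    from .estimation import average_estimates  # local import: avoid cycle

    def stratum(df: pd.DataFrame) -> Optional[dict]:
        if len(df) == 0:
            return None
        m = agreement_metrics(df["estimated_cm"], df["reference_cm"])
        pf = _per_fold(df, rmse)
        if pf:
            m["rmse_per_fold"] = pf
        return m

    overall = stratum(pairs)
    if overall is None:
        raise ValueError("report needs at least one estimate/reference pair")

    by_group: dict = {}
    if "group" in pairs.columns:
        for g, sub in pairs.groupby("group"):
            m = stratum(sub)
            if m is None:
                logger.info("omitting empty group stratum %s", g)
                continue
            by_group[str(g)] = m

    by_condition: dict = {}
    if "condition" in pairs.columns:
        for c, sub in pairs.groupby("condition"):
            m = stratum(sub)
            if m is None:
                logger.info("omitting empty condition stratum %s", c)
                continue
            by_condition[str(c)] = m

    by_averaging: dict = {}
    fold_rmses: dict[int, list[float]] = {}
    for n in sorted(set(int(n) for n in averaging_levels)):
        avg = average_estimates(pairs, n)
        m = stratum(avg) if len(avg) else None
        if m is None:
            logger.info("omitting empty averaging stratum n=%d", n)
            continue
        by_averaging[str(n)] = m
        pf = _per_fold(avg, rmse)
        if pf and len(pf["values"]) >= 2:
            fold_rmses[n] = pf["values"]

    anova = None
    if len(fold_rmses) >= 2:
        f, p = anova_averaging(fold_rmses)
        anova = {"F": f, "p": p, "levels": sorted(fold_rmses)}

    return AgreementReport(
        overall=overall,
        by_group=by_group,
        by_condition=by_condition,
        by_averaging=by_averaging,
        anova=anova,
    )
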