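"""Regression model zoo: family names, factories, and hyper-parameter grids.

Families mirror the usual tabular-gait lineup: linear regression (lr),
regression tree (tree), RBF support-vector regression (svm), k-nearest
neighbors (knn), and gradient-boosted trees (gbt, XGBoost).
"""

from __future__ import annotations

from typing import Mapping, Optional

from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

MODEL_FAMILIES = ("lr", "tree", "svm", "knn", "gbt")

#: default hyper-parameter search grids per family (grid-searched per fold
#: on the fold's training subjects only)
DEFAULT_GRIDS: Mapping[str, dict[str, list]] = {
    "lr": {},
    "tree": {"max_depth": [2, 4, 6, 10]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 0.01]},
    "knn": {"n_neighbors": [1, 5, 15, 25]},
    "gbt": {
        "max_depth": [2, 4, 6],
        "n_estimators": [200],
        "learning_rate": [0.05, 0.2],
    },
}


def make_model(family: str, seed: int = 0, **hyper):
    """Instantiate one model of the given family with the given hyper-params.

    Scale-sensitive families (svm, knn) get a standardization front end.
    """
    if family == "lr":
        return LinearRegression(**hyper)
    if family == "tree":
        return DecisionTreeRegressor(random_state=seed, **hyper)
    if family == "svm":
        svr_kwargs = dict(kernel="rbf")
        svr_kwargs.update(hyper)
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(**svr_kwargs))])
    if family == "knn":
        return Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsRegressor(**hyper))]
        )
    if family == "gbt":
        kwargs = dict(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            subsample=1.0,
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        kwargs.update(hyper)
        return XGBRegressor(**kwargs)
    raise ValueError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def grid_points(grid: Optional[Mapping[str, list]]) -> list[dict]:
    """Expand a hyper-parameter grid into a list of parameter dicts."""
    if not grid:
        return [{}]
    points: list[dict] = [{}]
    for key in sorted(grid):
        points = [dict(p, **{key: v}) for p in points for v in grid[key]]
    return points


def _strip_pipeline_prefix(family: str, hyper: dict) -> dict:
    """Map plain hyper names onto pipeline step parameters for svm/knn."""
    if family == "svm":
        return {f"svr__{k}": v for k, v in hyper.items()}
    if family == "knn":
        return {f"knn__{k}": v for k, v in hyper.items()}
    return hyper


def make_model_for_grid_point(family: str, seed: int, hyper: dict):
    """Like :func:`make_model` but accepts plain grid names for pipelines."""
    if family in ("svm", "knn"):
        model = make_model(family, seed)
        model.set_params(**_strip_pipeline_prefix(family, hyper))
        return model
    return make_model(family, seed, **hyper)
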