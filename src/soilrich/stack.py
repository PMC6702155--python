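"""Stacked tree-based spatial prediction of richness.

A random forest and a gradient-boosting regressor (learning rate fixed
at 0.05 — its effect can be compensated by the number of boosting
iterations) are trained independently and stacked by simple averaging.
Generalization error is estimated by nested cross-validation: the inner
folds select hyperparameters by R², the outer folds score the selected
stack on held-out sites, and the whole procedure is repeated with fresh
random splits to stabilise the estimates.  The shipped model is refit
on all data with the modal hyperparameters across outer folds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

__all__ = [
    "StackedModel",
    "PredictionRaster",
    "DEFAULT_GRID",
    "SMALL_GRID",
    "train_stack",
    "predict_raster",
]

#: documented default search grid (the tuned hyperparameters are the
#: number of trees, the feature subset size, tree depth and leaf size)
DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_features": [0.33, "sqrt", 1.0],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 3, 5],
}

#: reduced grid for quick runs and tests
SMALL_GRID = {
    "n_estimators": [100],
    "max_features": [0.33, 1.0],
    "max_depth": [None, 5],
    "min_samples_leaf": [1, 3],
}

LEARNING_RATE = 0.05
NODATA = -9999.0


@dataclass
class StackedModel:
    forest: RandomForestRegressor = field(repr=False)
    boosting: GradientBoostingRegressor = field(repr=False)
    features: list[str]
    forest_params: dict
    boosting_params: dict
    outer_r2: list[float]
    outer_rmse: list[float]
    n_repeats: int

    @property
    def r2(self) -> float:
        return float(np.mean(self.outer_r2))

    @property
    def rmse(self) -> float:
        return float(np.mean(self.outer_rmse))

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        return self.forest.predict(X), self.boosting.predict(X)

    def predict(self, X) -> np.ndarray:
        rf, gb = self.predict_components(X)
        return (rf + gb) / 2.0


@dataclass
class PredictionRaster:
    """Georeferenced grid of predictions (row 0 = northernmost)."""

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    nodata: float = NODATA

    @property
    def mask(self) -> np.ndarray:
        return self.values != self.nodata


def _make_learners(seed: int):
    rf = RandomForestRegressor(random_state=seed)
    gb = GradientBoostingRegressor(random_state=seed, learning_rate=LEARNING_RATE)
    return rf, gb


def _tune(model, grid, X, y, folds, seed):
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(model, grid, scoring="r2", cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_params_, search.best_estimator_


def train_stack(
    X: pd.DataFrame,
    y,
    grid: dict | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> StackedModel:
    """Train the averaged forest+boosting stack with nested CV.

    Inner ``folds``-fold CV selects hyperparameters for each learner by
    R²; the outer ``folds``-fold CV scores the selected stack on
    held-out sites; both are repeated ``repeats`` times with fresh
    splits.  Reported R²/RMSE are per-repeat means over outer folds.
    The final model is refit on all data with the modal outer-fold
    hyperparameters.  Deterministic given ``seed``.
    """
    if grid is not None and len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    grid = DEFAULT_GRID if grid is None else grid
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    features = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(Xv.shape[1])
    ]
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 50:
        raise ValueError("need at least 50 sites to train the stack")

    outer_r2, outer_rmse = [], []
    chosen_rf, chosen_gb = [], []
    for rep in range(repeats):
        rep_seed = (seed * 1009 + rep) % (2**31 - 1)
        outer = KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        preds = np.empty(n)
        for fold_i, (tr, te) in enumerate(outer.split(Xv)):
            inner_seed = (rep_seed + 31 * fold_i + 1) % (2**31 - 1)
            rf0, gb0 = _make_learners(inner_seed)
            rf_par, rf = _tune(rf0, grid, Xv[tr], y[tr], folds, inner_seed)
            gb_par, gb = _tune(gb0, grid, Xv[tr], y[tr], folds, inner_seed)
            chosen_rf.append(tuple(sorted(rf_par.items())))
            chosen_gb.append(tuple(sorted(gb_par.items())))
            preds[te] = (rf.predict(Xv[te]) + gb.predict(Xv[te])) / 2.0
        sst = np.sum((y - y.mean()) ** 2)
        outer_r2.append(float(1 - np.sum((y - preds) ** 2) / sst) if sst > 0 else 0.0)
        outer_rmse.append(float(np.sqrt(np.mean((y - preds) ** 2))))

    modal_rf = dict(Counter(chosen_rf).most_common(1)[0][0])
    modal_gb = dict(Counter(chosen_gb).most_common(1)[0][0])
    rf, gb = _make_learners(seed)
    rf.set_params(**modal_rf)
    gb.set_params(**modal_gb)
    rf.fit(Xv, y)
    gb.fit(Xv, y)
    return StackedModel(
        forest=rf,
        boosting=gb,
        features=features,
        forest_params=modal_rf,
        boosting_params=modal_gb,
        outer_r2=outer_r2,
        outer_rmse=outer_rmse,
        n_repeats=repeats,
    )


def predict_raster(
    model: StackedModel,
    grids: dict[str, np.ndarray],
    lat: np.ndarray,
    lon: np.ndarray,
    nodata: float = NODATA,
) -> PredictionRaster:
    """Predict richness on covariate grids.

    ``grids`` maps each model feature to a 2-D array on a shared
    lat/lon grid; cells where any covariate is non-finite become
    nodata.  Returns a georeferenced prediction grid.
    """
    missing = [f for f in model.features if f not in grids]
    if missing:
        raise KeyError(f"covariate grids missing features: {missing}")
    shapes = {g.shape for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError(f"covariate grids disagree in shape: {shapes}")
    shape = shapes.pop()
    if shape != (len(lat), len(lon)):
        raise ValueError("grid shape does not match lat/lon axes")
    stackmat = np.stack([np.asarray(grids[f], dtype=float) for f in model.features])
    valid = np.all(np.isfinite(stackmat), axis=0)
    out = np.full(shape, float(nodata))
    if valid.any():
        Xv = stackmat[:, valid].T
        out[valid] = model.predict(Xv)
    return PredictionRaster(values=out, lat=np.asarray(lat), lon=np.asarray(lon),
                            nodata=nodata)
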