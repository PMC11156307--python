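"""Tree-ensemble species abundance models.

Per species, two regressors are tuned and fitted on survey CPUE against six
environmental covariates: a random forest (RF) and boosted regression trees
(BRT). Hyperparameters are chosen by exhaustive grid search with k-fold
cross-validated RMSE inside the training split; the final ensemble predicts
the inverse-RMSE-weighted average of the two members, so the member with the
lower holdout error receives the strictly larger weight. Negative weighted
predictions are floored at zero, as CPUE is a non-negative density.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .config import ENV_VARIABLES

FEATURES = list(ENV_VARIABLES)

#: default hyperparameter search grids; the real tuning exercise evaluated
#: 2700 combinations per species, which these compact defaults stand in for
DEFAULT_RF_GRID = {
    "n_trees": [200, 500],
    "max_features": [2, 3, 4],
    "min_node_size": [1, 5, 10],
}
DEFAULT_BRT_GRID = {
    "n_trees": [200, 500],
    "learning_rate": [0.01, 0.05, 0.1],
    "interaction_depth": [2, 3, 5],
}


@dataclass
class TunedModelSpec:
    """Winning hyperparameter combination for one algorithm."""

    algorithm: str  # 'rf' or 'brt'
    params: dict
    cv_rmse: float = float("nan")

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "brt"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def make_estimator(spec: TunedModelSpec, seed: int):
    p = spec.params
    if spec.algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=int(p["n_trees"]),
            max_features=min(int(p["max_features"]), len(FEATURES)),
            min_samples_leaf=int(p["min_node_size"]),
            random_state=seed,
            n_jobs=1,
        )
    return GradientBoostingRegressor(
        n_estimators=int(p["n_trees"]),
        learning_rate=float(p["learning_rate"]),
        max_depth=int(p["interaction_depth"]),
        random_state=seed,
    )


def _complexity_key(algorithm: str, params: Mapping, index: int):
    # ties: fewer trees first, then the simpler model, then grid order
    if algorithm == "rf":
        return (
            params["n_trees"],
            params["max_features"],
            -params["min_node_size"],
            index,
        )
    return (params["n_trees"], params["interaction_depth"], index)


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test row partition, stratified by survey year.

    Global sizes are floor(fraction * n) and the remainder. Within each
    year rows are shuffled with the given seed; every year contributes at
    least one training row so no survey year is unseen at fit time.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)

    years = sorted(table["year"].unique())
    perms = {}
    take = {}
    frac = {}
    for y in years:
        idx = table.index[table["year"] == y].to_numpy()
        perms[y] = idx[rng.permutation(idx.size)]
        exact = fraction * idx.size
        take[y] = min(idx.size, max(1, int(np.floor(exact))))
        frac[y] = exact - np.floor(exact)

    total = sum(take.values())
    if total < n_train:
        order = sorted(years, key=lambda y: (-frac[y], y))
        for y in itertools.cycle(order):
            if total == n_train:
                break
            if take[y] < len(perms[y]):
                take[y] += 1
                total += 1
    elif total > n_train:
        order = sorted(years, key=lambda y: (frac[y], y))
        for y in itertools.cycle(order):
            if total == n_train:
                break
            if take[y] > 1:
                take[y] -= 1
                total -= 1

    train_idx = np.concatenate([perms[y][: take[y]] for y in years])
    test_idx = np.concatenate([perms[y][take[y]:] for y in years])
    return table.loc[train_idx], table.loc[test_idx]


def _rmse(y_true, y_pred) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def tune_hyperparameters(
    train: pd.DataFrame,
    algorithm: str,
    grid: Mapping[str, Sequence] | None = None,
    cv: int = 5,
    seed: int = 0,
    features: Sequence[str] = FEATURES,
    response: str = "cpue",
) -> TunedModelSpec:
    """Exhaustive grid search minimising k-fold cross-validated RMSE.

    Every grid point is evaluated on the same fold partition; the argmin is
    returned with ties broken towards the simpler model. A degenerate
    response (all values identical) short-circuits to the simplest grid
    point with a warning.
    """
    if grid is None:
        grid = DEFAULT_RF_GRID if algorithm == "rf" else DEFAULT_BRT_GRID
    candidates = _expand_grid(grid)
    if not candidates:
        raise ValueError("hyperparameter grid is empty")
    if len(train) < cv:
        raise ValueError(f"training set has fewer rows ({len(train)}) than folds ({cv})")

    X = train[list(features)].to_numpy(dtype=float)
    y = train[response].to_numpy(dtype=float)

    if np.ptp(y) == 0:
        warnings.warn(
            "degenerate response (all CPUE identical); returning simplest grid point",
            stacklevel=2,
        )
        simplest = min(
            range(len(candidates)),
            key=lambda i: _complexity_key(algorithm, candidates[i], i),
        )
        return TunedModelSpec(algorithm, candidates[simplest], cv_rmse=0.0)

    folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(X))
    best = None
    for i, params in enumerate(candidates):
        fold_rmse = []
        for tr, va in folds:
            est = make_estimator(TunedModelSpec(algorithm, params), seed)
            est.fit(X[tr], y[tr])
            fold_rmse.append(_rmse(y[va], est.predict(X[va])))
        score = float(np.mean(fold_rmse))
        key = (score, *_complexity_key(algorithm, params, i))
        if best is None or key < best[0]:
            best = (key, params, score)
    return TunedModelSpec(algorithm, best[1], cv_rmse=best[2])


@dataclass
class EnsembleModel:
    """Weighted RF + BRT ensemble for one species.

    Weights are w_m = (1/RMSE_m) / sum_k (1/RMSE_k) from the holdout RMSEs,
    so the more accurate member dominates; equal RMSEs give 0.5/0.5 and a
    doubly degenerate (both-zero) holdout falls back to equal weights.
    """

    species: str
    rf: RandomForestRegressor
    brt: GradientBoostingRegressor
    w_rf: float
    w_brt: float
    rmse_rf: float
    rmse_brt: float
    var_explained: float
    features: list[str] = field(default_factory=lambda: list(FEATURES))
    log1p_response: bool = False
    holdout_X: np.ndarray | None = None
    holdout_y: np.ndarray | None = None

    def _member_predict(self, est, X: np.ndarray) -> np.ndarray:
        pred = est.predict(X)
        return np.expm1(pred) if self.log1p_response else pred

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-average prediction on the CPUE scale, floored at 0."""
        pred = self.w_rf * self._member_predict(self.rf, X) + (
            self.w_brt * self._member_predict(self.brt, X)
        )
        return np.clip(pred, 0.0, None)


def inverse_rmse_weights(rmse_a: float, rmse_b: float) -> tuple[float, float]:
    if rmse_a == 0.0 and rmse_b == 0.0:
        return 0.5, 0.5
    if rmse_a == 0.0:
        return 1.0, 0.0
    if rmse_b == 0.0:
        return 0.0, 1.0
    inv = np.array([1.0 / rmse_a, 1.0 / rmse_b])
    w = inv / inv.sum()
    return float(w[0]), float(w[1])


def fit_ensemble(
    train: pd.DataFrame,
    test: pd.DataFrame,
    rf_spec: TunedModelSpec,
    brt_spec: TunedModelSpec,
    seed: int = 0,
    species: str = "",
    features: Sequence[str] = FEATURES,
    response: str = "cpue",
    log1p_response: bool = False,
) -> EnsembleModel:
    """Fit both members on the training split and weight them on the holdout."""
    feats = list(features)
    Xtr = train[feats].to_numpy(dtype=float)
    ytr = train[response].to_numpy(dtype=float)
    Xte = test[feats].to_numpy(dtype=float)
    yte = test[response].to_numpy(dtype=float)
    if log1p_response:
        ytr = np.log1p(ytr)

    rf = make_estimator(rf_spec, seed).fit(Xtr, ytr)
    brt = make_estimator(brt_spec, seed).fit(Xtr, ytr)

    def back(pred):
        return np.expm1(pred) if log1p_response else pred

    rmse_rf = _rmse(yte, back(rf.predict(Xte)))
    rmse_brt = _rmse(yte, back(brt.predict(Xte)))
    w_rf, w_brt = inverse_rmse_weights(rmse_rf, rmse_brt)

    ens_pred = np.clip(w_rf * back(rf.predict(Xte)) + w_brt * back(brt.predict(Xte)), 0, None)
    sst = float(np.sum((yte - yte.mean()) ** 2))
    sse = float(np.sum((yte - ens_pred) ** 2))
    var_explained = 1.0 - sse / sst if sst > 0 else float("nan")

    return EnsembleModel(
        species=species,
        rf=rf,
        brt=brt,
        w_rf=w_rf,
        w_brt=w_brt,
        rmse_rf=rmse_rf,
        rmse_brt=rmse_brt,
        var_explained=var_explained,
        features=feats,
        log1p_response=log1p_response,
        holdout_X=Xte,
        holdout_y=yte,
    )


def predict_surface(model: EnsembleModel, env: xr.Dataset) -> xr.DataArray:
    """Predicted abundance density (kg/km2) on an environmental stack.

    Cells where any covariate is masked propagate as masked.
    """
    missing = [f for f in model.features if f not in env.data_vars]
    if missing:
        raise ValueError(f"environment stack is missing covariates: {missing}")
    cols = [env[f].values for f in model.features]
    valid = np.all([np.isfinite(c) for c in cols], axis=0)
    out = np.full(valid.shape, np.nan)
    if valid.any():
        X = np.column_stack([c[valid] for c in cols])
        out[valid] = model.predict(X)
    da = xr.DataArray(
        out,
        dims=("lat", "lon"),
        coords={"lat": env["lat"], "lon": env["lon"]},
        name=model.species or "abundance",
        attrs={
            "variable": "abundance",
            "units": "kg/km2",
            "species": model.species,
            "period": str(env.attrs.get("period", "")),
            "scenario": str(env.attrs.get("scenario", "")),
        },
    )
    return da


def variable_importance(
    model: EnsembleModel, n_repeats: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Permutation importance on the holdout, weight-averaged over members.

    For each member, the increase in holdout RMSE when one covariate is
    permuted (mean over repeats) is the member importance; member values are
    combined with the ensemble weights, negatives truncated to zero, and the
    result normalised to sum to one. Returns a table sorted by importance.
    """
    if model.holdout_X is None or model.holdout_y is None:
        raise ValueError("model carries no holdout data")
    rng = np.random.default_rng(seed)
    X, y = model.holdout_X, model.holdout_y
    members = [(model.rf, model.w_rf), (model.brt, model.w_brt)]
    imp = np.zeros(len(model.features))
    for est, w in members:
        if w == 0.0:
            continue
        base = _rmse(y, model._member_predict(est, X))
        for j in range(len(model.features)):
            deltas = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                deltas.append(_rmse(y, model._member_predict(est, Xp)) - base)
            imp[j] += w * float(np.mean(deltas))
    imp = np.clip(imp, 0.0, None)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    df = pd.DataFrame({"covariate": model.features, "importance": imp})
    return df.sort_values("importance", ascending=False, ignore_index=True)
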