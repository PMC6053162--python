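"""Regressor roster and nested k-fold cross-validation.

Seven regressors forecast the 14-day maximum SCr (or minimum 1/SCr):
linear regression, ridge, lasso, LARS, SGD, random forest, and MARS
when a py-earth backend is importable (otherwise the roster shrinks
with a warning).  Hyperparameters are tuned by an inner k-fold CV on
mean validation MSE on the working scale; the outer CV provides the
unbiased performance estimate.  Predictions are mapped back to the SCr
scale, staged through the detection/staging criteria, and scored as
regression, 4-class stage classification, and binary occurrence
classification.

Everything is deterministic given the seed: fold assignment, stochastic
learners, and leakage-safe per-fold post-processing all derive
sub-seeds from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lars, Lasso, LinearRegression, Ridge, SGDRegressor

from . import metrics as metrics_mod
from .criteria import label_horizon
from .features import (FeatureMatrix, invert_prediction, make_postprocessor,
                       DEFAULT_SCR_CAP)

try:  # optional MARS backend; unmaintained upstream, never required
    from pyearth import Earth  # pragma: no cover
    HAS_MARS = True  # pragma: no cover
except ImportError:
    Earth = None
    HAS_MARS = False


def _roster() -> dict:
    """name -> (factory(seed), default hyperparameter grid)."""
    roster = {
        "linear": (lambda seed: LinearRegression(), {}),
        "ridge": (lambda seed: Ridge(),
                  {"alpha": [0.01, 0.1, 1.0, 10.0]}),
        "lasso": (lambda seed: Lasso(max_iter=20000),
                  {"alpha": [0.01, 0.1, 1.0, 10.0]}),
        "lars": (lambda seed: Lars(),
                 {"n_nonzero_coefs": [5, 10, np.inf]}),
        "sgd": (lambda seed: SGDRegressor(random_state=seed, max_iter=2000),
                {"alpha": [1e-4, 1e-3], "penalty": ["l2", "l1"]}),
        "random_forest": (
            lambda seed: RandomForestRegressor(random_state=seed, n_jobs=1),
            {"n_estimators": [100], "max_depth": [None, 10]}),
    }
    if HAS_MARS:
        roster["mars"] = (lambda seed: Earth(),
                          {"max_terms": [10, 20]})  # pragma: no cover
    return roster


MODEL_ROSTER = _roster()


@dataclass
class ModelSpec:
    name: str
    grid: dict | None = None

    def __post_init__(self):
        if self.name == "mars" and not HAS_MARS:
            raise ValueError(
                "MARS requested but no py-earth backend is installed; "
                "available models: %s" % sorted(MODEL_ROSTER))
        if self.name not in MODEL_ROSTER:
            raise ValueError(f"unknown model {self.name!r}; "
                             f"roster: {sorted(MODEL_ROSTER)}")
        if self.grid is None:
            self.grid = MODEL_ROSTER[self.name][1]

    def make(self, seed: int):
        return MODEL_ROSTER[self.name][0](seed)


def available_models() -> list[str]:
    models = sorted(MODEL_ROSTER)
    if not HAS_MARS:
        warnings.warn("MARS backend unavailable; roster reduced to %s"
                      % models, stacklevel=2)
    return models


@dataclass
class CVConfig:
    k_outer: int = 3
    k_inner: int = 3
    seed: int = 0
    grouping: str = "by_row"          # or "by_patient"
    leakage_safe: bool = False        # fit post-processing inside outer-train
    scr_cap: float = DEFAULT_SCR_CAP

    def __post_init__(self):
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("both CV loops need k >= 2")
        if self.grouping not in ("by_row", "by_patient"):
            raise ValueError("grouping must be by_row or by_patient")


def make_folds(n_rows: int, k: int, seed: int, groups=None) -> np.ndarray:
    """Deterministic near-equal fold assignment; with ``groups`` all rows
    of a group share a fold."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    if groups is None:
        if n_rows < k:
            raise ValueError("fewer rows than folds")
        perm = rng.permutation(n_rows)
        folds = np.empty(n_rows, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = f
        return folds
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise ValueError("fewer groups than folds")
    perm = rng.permutation(len(uniq))
    gfold = {}
    for f, chunk in enumerate(np.array_split(perm, k)):
        for gi in chunk:
            gfold[uniq[gi]] = f
    return np.array([gfold[g] for g in groups], dtype=int)


def _param_grid(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    combos = [{}]
    for key in keys:
        combos = [dict(c, **{key: v}) for c in combos for v in grid[key]]
    return combos


class TunedRegressor(BaseEstimator, RegressorMixin):
    """Regressor with inner-CV hyperparameter selection.

    ``fit`` runs k_inner-fold CV over the grid, picks the combination
    with the lowest mean validation MSE (on the working target scale),
    and refits it on the full training set.  Fitted attributes:
    ``best_params_``, ``best_estimator_``, ``inner_mse_``.
    """

    def __init__(self, model: str = "ridge", grid: dict | None = None,
                 k_inner: int = 3, seed: int = 0):
        self.model = model
        self.grid = grid
        self.k_inner = k_inner
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        spec = ModelSpec(self.model, self.grid)
        combos = _param_grid(spec.grid)
        folds = make_folds(len(y), self.k_inner, self.seed)
        self.inner_mse_ = {}
        for params in combos:
            errs = []
            for f in range(self.k_inner):
                tr, va = folds != f, folds == f
                est = spec.make(self.seed).set_params(**_finite(params))
                est.fit(X[tr], y[tr])
                errs.append(float(np.mean((est.predict(X[va]) - y[va]) ** 2)))
            self.inner_mse_[json.dumps(params, default=str)] = float(np.mean(errs))
        best = min(combos, key=lambda p: self.inner_mse_[json.dumps(p, default=str)])
        self.best_params_ = best
        self.best_estimator_ = spec.make(self.seed).set_params(**_finite(best))
        self.best_estimator_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.best_estimator_.predict(np.asarray(X, dtype=float))


def _finite(params: dict) -> dict:
    """Map the `all coefficients` LARS sentinel (inf) to the sklearn form."""
    out = {}
    for k, v in params.items():
        if k == "n_nonzero_coefs" and np.isinf(v):
            out[k] = 500
        else:
            out[k] = v
    return out


def fit_predict(spec: ModelSpec, hyperparams: dict, X_train, y_train,
                X_test, seed: int = 0) -> np.ndarray:
    """Fit one configuration and predict the test rows (working scale)."""
    est = spec.make(seed).set_params(**_finite(hyperparams))
    est.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return est.predict(np.asarray(X_test, dtype=float))


def _stage_predictions(scr_pred: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
    """Stage each predicted 14-day max SCr against its row's references."""
    init = meta["initial_scr"].to_numpy(dtype=float)
    rec = meta["recent_scr"].to_numpy(dtype=float)
    stages = np.empty(len(scr_pred), dtype=int)
    for i, p in enumerate(scr_pred):
        stages[i] = label_horizon(
            [float(p)],
            None if np.isnan(init[i]) else float(init[i]),
            None if np.isnan(rec[i]) else float(rec[i]))
    return stages


@dataclass
class CVReport:
    """Nested-CV result: per-fold and mean metrics, replay information."""

    model: str
    transform: str
    config: dict
    fold_metrics: list = field(default_factory=list)
    mean_metrics: dict = field(default_factory=dict)
    chosen_params: list = field(default_factory=list)
    fold_assignment: list = field(default_factory=list)
    postprocess_params: list = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("postprocess_params")
        return json.dumps(d, indent=2, default=str)


def nested_cv(matrix: FeatureMatrix, model: str | ModelSpec,
              cv: CVConfig | None = None) -> CVReport:
    """Nested k-fold CV of one model on one feature matrix.

    In leakage-safe mode the squeeze/z-score post-processing is fitted
    on each outer-train split only; otherwise the matrix is used as
    given (fit the post-processing on the whole matrix beforehand for
    the global-normalization variant).
    """
    cv = cv or CVConfig()
    spec = model if isinstance(model, ModelSpec) else ModelSpec(model)
    groups = (matrix.meta["patient_id"].to_numpy()
              if cv.grouping == "by_patient" else None)
    folds = make_folds(len(matrix), cv.k_outer, cv.seed, groups)
    ss = np.random.SeedSequence([int(cv.seed), 0xCE])
    fold_seeds = [int(c.generate_state(1)[0] % (2**31 - 1))
                  for c in ss.spawn(cv.k_outer)]

    report = CVReport(model=spec.name, transform=matrix.transform,
                      config={"k_outer": cv.k_outer, "k_inner": cv.k_inner,
                              "seed": cv.seed, "grouping": cv.grouping,
                              "leakage_safe": cv.leakage_safe},
                      fold_assignment=folds.tolist())
    X_all = np.asarray(matrix.X, dtype=float)

    for f in range(cv.k_outer):
        tr, te = folds != f, folds == f
        X_train, X_test = X_all[tr], X_all[te]
        if cv.leakage_safe:
            post = make_postprocessor().fit(X_train)
            X_train = post.transform(X_train)
            X_test = post.transform(X_test)
            report.postprocess_params.append({
                "lower": post["squeeze"].lower_bounds_.tolist(),
                "upper": post["squeeze"].upper_bounds_.tolist(),
                "mean": post["zscore"].mean_.tolist(),
                "scale": post["zscore"].scale_.tolist()})
        tuned = TunedRegressor(spec.name, spec.grid, cv.k_inner,
                               seed=fold_seeds[f])
        tuned.fit(X_train, matrix.y[tr])
        report.chosen_params.append(tuned.best_params_)
        pred_working = tuned.predict(X_test)
        pred_scr = invert_prediction(pred_working, matrix.transform, cv.scr_cap)
        pred_stage = _stage_predictions(pred_scr, matrix.meta.iloc[te])
        bundle = metrics_mod.evaluate_predictions(
            pred_scr, pred_stage,
            matrix.meta["target_scr"].to_numpy(dtype=float)[te],
            matrix.meta["true_stage"].to_numpy(dtype=int)[te])
        report.fold_metrics.append(bundle.as_dict())

    keys = report.fold_metrics[0].keys()
    report.mean_metrics = {
        k: float(np.mean([fm[k] for fm in report.fold_metrics]))
        for k in keys if isinstance(report.fold_metrics[0][k], (int, float))}
    return report
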