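"""The five prediction-model families behind one train/predict contract.

* ``LR``      — unregularized logistic regression (Newton-CG, 10,000 iters)
* ``LR_reg``  — L2 (ridge) logistic regression, penalty tuned by nested
                stratified 5-fold AUROC
* ``LR_ELN``  — elastic-net logistic regression (saga), mixing parameter and
                strength tuned likewise; internal feature selection via
                nonzero coefficients
* ``RF``      — random forest; trees/depth/min-split/min-leaf/features-per-
                split tuned likewise; internal selection via impurity
                importances
* ``MLP``     — two-hidden-layer network (Leaky ReLU, dropout, batch norm)
                with a successive-halving hyperparameter search

All families except the scale-invariant RF consume features standardized
with statistics from the training rows only; constant training columns are
dropped with a warning.  Hyperparameter grids are explicit package defaults
chosen for desk runtime; ``search_budget`` scales the MLP search (20 by
default, 500 at full scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from . import _mlp
from .metrics import auroc

FAMILIES = ("LR", "LR_reg", "LR_ELN", "RF", "MLP")

#: explicit tuning grids (logged defaults; the contracts hold for any values)
RIDGE_C_GRID = tuple(np.logspace(-3, 3, 7))
ELN_C_GRID = tuple(np.logspace(-2, 2, 5))
ELN_L1_RATIO_GRID = (0.1, 0.5, 0.9)
RF_GRID = {
    "n_estimators": [200],
    "max_depth": [None, 10],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 2],
    "max_features": ["sqrt"],
}


@dataclass
class ModelConfig:
    family: str = "LR"
    tuning_folds: int = 5
    search_budget: int = 20
    max_epochs: int = 250
    reduction_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")
        if self.reduction_factor < 2:
            raise ValueError("reduction_factor must be >= 2")

    @classmethod
    def full_scale(cls, family: str = "MLP", **kw) -> "ModelConfig":
        """The full-size MLP search (500 configurations)."""
        return cls(family=family, search_budget=500, **kw)


@dataclass
class FittedModel:
    family: str
    estimator: Any
    feature_names: list[str]
    kept_mask: np.ndarray            # constant training columns dropped
    mean: np.ndarray
    sd: np.ndarray
    hyperparams: dict
    train_auroc: float
    degenerate: bool = False         # no usable features: constant scores

    @property
    def has_internal_selection(self) -> bool:
        return self.family in ("LR_ELN", "RF")


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} constant feature column(s)",
                      stacklevel=3)
    return kept, mean, sd


def _cv(config: ModelConfig, y: np.ndarray) -> StratifiedKFold:
    k = min(config.tuning_folds, int((y == 1).sum()), int((y == 0).sum()))
    if k < 2:
        raise ValueError("need at least 2 subjects per class for tuning CV")
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed % (2**31))


def train_model(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
) -> FittedModel:
    """Fit one model family on (X, y); X is subjects x features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be subjects x features aligned with y")
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes to train")
    if X.shape[1] == 0:
        raise ValueError("empty feature matrix")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(X.shape[1])
    ]

    kept, mean, sd = _standardize_fit(X)
    if not kept.any():
        # nothing informative at all: constant no-skill model
        model = FittedModel(config.family, None, names, kept, mean, sd, {}, 0.5,
                            degenerate=True)
        return model
    sd_safe = np.where(kept, sd, 1.0)
    Z = (X[:, kept] - mean[kept]) / sd_safe[kept]

    hyper: dict = {}
    if config.family == "LR":
        est = LogisticRegression(C=np.inf, solver="newton-cg", max_iter=10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Z, y)
    elif config.family == "LR_reg":
        gs = GridSearchCV(
            LogisticRegression(solver="lbfgs", max_iter=10000),
            {"C": list(RIDGE_C_GRID)}, scoring="roc_auc", cv=_cv(config, y),
        )
        gs.fit(Z, y)
        est = gs.best_estimator_
        hyper = dict(gs.best_params_)
    elif config.family == "LR_ELN":
        gs = GridSearchCV(
            LogisticRegression(solver="saga", max_iter=10000, tol=1e-3),
            {"C": list(ELN_C_GRID), "l1_ratio": list(ELN_L1_RATIO_GRID)},
            scoring="roc_auc", cv=_cv(config, y),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gs.fit(Z, y)
        est = gs.best_estimator_
        hyper = dict(gs.best_params_)
    elif config.family == "RF":
        gs = GridSearchCV(
            RandomForestClassifier(random_state=config.seed % (2**31)),
            RF_GRID, scoring="roc_auc", cv=_cv(config, y),
        )
        gs.fit(X[:, kept], y)  # RF is scale-invariant: raw features
        est = gs.best_estimator_
        hyper = dict(gs.best_params_)
    else:  # MLP
        net, hp, val_auroc = _mlp.tune_and_fit(
            Z, y, search_budget=config.search_budget,
            max_epochs=config.max_epochs,
            reduction_factor=config.reduction_factor, seed=config.seed,
        )
        est = net
        hyper = {**hp.__dict__, "search_val_auroc": val_auroc}

    model = FittedModel(config.family, est, names, kept, mean, sd_safe, hyper, 0.5)
    model.train_auroc = auroc(predict_scores(model, X, names), y)
    return model


def predict_scores(
    model: FittedModel,
    X: np.ndarray,
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """Per-subject scores in [0, 1] using the stored training statistics."""
    X = np.asarray(X, dtype=float)
    if feature_names is not None:
        names = list(feature_names)
        if names != model.feature_names:
            if set(names) == set(model.feature_names):
                idx = [names.index(f) for f in model.feature_names]
                X = X[:, idx]
            else:
                missing = sorted(set(model.feature_names) - set(names))
                extra = sorted(set(names) - set(model.feature_names))
                raise ValueError(
                    f"feature mismatch: missing={missing[:5]}, unexpected={extra[:5]}"
                )
    if X.shape[1] != len(model.feature_names):
        raise ValueError("feature mismatch: wrong number of columns")
    if model.degenerate:
        return np.full(X.shape[0], 0.5)
    kept = model.kept_mask
    if model.family == "RF":
        return model.estimator.predict_proba(X[:, kept])[:, 1]
    Z = (X[:, kept] - model.mean[kept]) / model.sd[kept]
    if model.family == "MLP":
        return model.estimator.predict_proba(Z)
    return model.estimator.predict_proba(Z)[:, 1]


def internal_selection_report(model: FittedModel):
    """Per-feature (selected, rank) for the internally selecting families.

    Elastic net: selected iff coefficient nonzero, ranked by |coefficient|
    descending.  Random forest: ranked by impurity importance descending,
    selected iff importance exceeds the uniform share 1/p.  Ranks start at 1.
    """
    import pandas as pd

    if not model.has_internal_selection:
        raise ValueError(f"family {model.family} has no internal feature selection")
    names = np.array(model.feature_names)
    p = len(names)
    weight = np.zeros(p)
    if model.degenerate:
        selected = np.zeros(p, dtype=bool)
    elif model.family == "LR_ELN":
        weight[model.kept_mask] = np.abs(model.estimator.coef_.ravel())
        selected = weight > 0
    else:
        weight[model.kept_mask] = model.estimator.feature_importances_
        selected = weight > 1.0 / p
    rank = rankdata(-weight, method="min").astype(int)
    return pd.DataFrame({"feature": names, "selected": selected,
                         "weight": weight, "rank": rank}).set_index("feature")
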