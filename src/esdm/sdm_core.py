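"""Base species-distribution learners behind one fit/predict contract.

Three algorithms are supported:

``maxent_like``
    L1-regularized logistic regression on presence vs pseudo-absence with
    linear + quadratic expansions of the continuous covariates — the
    standard presence/background logistic reformulation of maximum-entropy
    modelling.
``random_forest``
    500 trees, sqrt feature subsampling, vote-fraction probabilities.
``svm``
    RBF-kernel SVC with Platt-scaled probabilities.

All stochastic elements consume the caller's seed; continuous features are
standardized internally with training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from esdm.env_layers import EnvStack, Layer
from esdm.errors import ContractError, SchemaError
from esdm.occurrence import extract_covariates

ALGORITHMS = ("maxent_like", "random_forest", "svm")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "maxent_like": {"C": 1.0},
    "random_forest": {"n_estimators": 500},
    "svm": {"C": 1.0, "gamma": "scale"},
}


@dataclass
class SDMFit:
    algorithm: str
    model: object
    columns: list[str]
    continuous_cols: list[str]
    means: np.ndarray
    sds: np.ndarray
    seed: int
    training_auc: float = float("nan")

    def design_matrix(self, X: pd.DataFrame) -> np.ndarray:
        """Map a raw design table onto the training feature space."""
        missing = [c for c in self.columns if c not in X.columns]
        for col in list(missing):
            # one-hot columns for codes absent at prediction time are all-zero
            base = col.split("=", 1)[0]
            if "=" in col and base in {c.split("=", 1)[0] for c in X.columns}:
                X = X.assign(**{col: 0.0})
                missing.remove(col)
        if missing:
            raise SchemaError(f"prediction stack lacks features: {missing}")
        Z = X[self.columns].to_numpy(dtype=float)
        Z = (Z - self.means) / self.sds
        if self.algorithm == "maxent_like":
            cont_idx = [self.columns.index(c) for c in self.continuous_cols]
            Z = np.column_stack([Z, Z[:, cont_idx] ** 2])
        return Z

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.design_matrix(X)
        proba = self.model.predict_proba(Z)[:, 1]
        return np.clip(proba, 0.0, 1.0)


def _make_estimator(algorithm: str, hyperparams: Mapping, seed: int):
    if algorithm == "maxent_like":
        return LogisticRegression(
            l1_ratio=1.0,  # lasso penalty
            C=float(hyperparams.get("C", 1.0)),
            solver="liblinear",
            random_state=seed,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hyperparams.get("n_estimators", 500)),
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "svm":
        svc = SVC(
            kernel="rbf",
            C=float(hyperparams.get("C", 1.0)),
            gamma=hyperparams.get("gamma", "scale"),
            random_state=seed,
        )
        # Platt scaling on internal (unshuffled, deterministic) folds
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    raise ContractError(f"unknown algorithm {algorithm!r}")


def fit_sdm(
    algorithm: str,
    X: pd.DataFrame,
    y,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> SDMFit:
    """Fit one base learner. Deterministic given (X, y, hyperparams, seed)."""
    y = np.asarray(y, dtype=int)
    if len(X) < 20:
        raise ContractError("need at least 20 training rows")
    if len(np.unique(y)) < 2:
        raise ContractError("both classes must be present in y")
    values = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ContractError("non-finite features in design table")
    hp = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    hp.update(hyperparams or {})

    columns = list(X.columns)
    # one-hot categorical columns are named "layer=code" and left unexpanded
    is_indicator = ["=" in c for c in columns]
    continuous_cols = [c for c, ind in zip(columns, is_indicator) if not ind]

    means = values.mean(axis=0)
    sds = values.std(axis=0)
    sds[sds == 0] = 1.0
    for j, ind in enumerate(is_indicator):
        if ind:
            means[j], sds[j] = 0.0, 1.0

    fit = SDMFit(
        algorithm=algorithm,
        model=None,
        columns=columns,
        continuous_cols=continuous_cols,
        means=means,
        sds=sds,
        seed=seed,
    )
    Z = fit.design_matrix(X)
    fit.model = _make_estimator(algorithm, hp, seed)
    fit.model.fit(Z, y)

    from esdm.ensemble_eval import auc_score  # local import avoids a cycle

    fit.training_auc = auc_score(y, fit.model.predict_proba(Z)[:, 1])
    return fit


def predict_sdm(fit: SDMFit, stack: EnvStack) -> Layer:
    """Suitability raster in [0, 1] over the stack's valid cells."""
    grid = stack.grid
    mask = stack.valid_mask
    cells = np.flatnonzero(mask.ravel())
    X = extract_covariates(cells, stack)
    scores = fit.predict(X)
    out = np.full((grid.n_rows, grid.n_cols), np.nan)
    out.ravel()[cells] = scores
    return Layer(f"suitability_{fit.algorithm}", "continuous", out, grid)
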