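"""Delta-feature construction and the three progression classifiers.

The delta feature of each robust texture feature is the arithmetic
difference between its value at the final and baseline scans,
``delta_f = f_final - f_base``; any per-sample offset common to both
time points cancels. Three classifiers operate on the delta matrix:

* **Parenclitic network** — for every unordered pair of features an
  RBF-kernel SVM is trained on the two-column submatrix vs outcome; a
  sample's network has features as vertices and the pairwise predicted
  progression probability as edge weights. The mean vertex degree
  (2 * sum of edge weights / n_features) summarises the network, and a
  binomial GLM with logistic link maps mean degree to the progression
  probability.
* **LASSO logistic regression** — L1-penalised, penalty chosen by
  inner stratified CV within the training fold, columns standardised
  on training statistics.
* **Random forest** — 500 trees, maximum depth 10, fixed seed 42 by
  default.

All estimators follow the scikit-learn fit/predict_proba contract so
the LOOCV driver can treat them uniformly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "compute_delta",
    "delta_matrix",
    "DeltaFeatureMatrix",
    "ParencliticClassifier",
    "make_lasso",
    "make_rf",
    "get_model",
    "MODEL_NAMES",
]

log = logging.getLogger(__name__)

MODEL_NAMES = ("parenclitic", "lasso", "rf")


def compute_delta(base: pd.Series, final: pd.Series) -> pd.Series:
    """Element-wise final - base with feature names preserved."""
    base = pd.Series(base, dtype=float)
    final = pd.Series(final, dtype=float)
    if list(base.index) != list(final.index):
        raise ValueError("baseline and final feature names differ")
    return final - base


@dataclass
class DeltaFeatureMatrix:
    """Samples x delta-features table plus binary progression outcome."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.isna().any().any():
            raise ValueError("delta matrix contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")


def delta_matrix(
    base: pd.DataFrame,
    final: pd.DataFrame,
    outcome: np.ndarray,
    columns: list[str] | None = None,
) -> DeltaFeatureMatrix:
    """Build the delta matrix over (optionally) a robust feature subset.

    ``columns`` is typically the robust feature set from the
    calibration stage, possibly spanning both modalities (columns from
    T2WI and ADC extraction are simply concatenated).
    """
    if columns is not None:
        base, final = base[columns], final[columns]
    if list(base.columns) != list(final.columns) or not base.index.equals(
        final.index
    ):
        raise ValueError("baseline/final tables are not aligned")
    return DeltaFeatureMatrix(X=final - base, y=outcome)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")


class ParencliticClassifier(BaseEstimator, ClassifierMixin):
    """Parenclitic-network progression classifier.

    For each of the C(p, 2) feature pairs an RBF-kernel SVM with a
    Platt-style probabilistic output is trained on the two features vs
    the outcome (inputs standardised on training statistics, as the
    classical SVM implementations do by default). Edge weight
    ``p_ij`` of a sample's network is the pair classifier's predicted
    progression probability; the weighted degree of vertex i is
    ``sum_j p_ij`` and the network read-out is the mean vertex degree
    ``2 * sum_{i<j} p_ij / p`` in [0, p - 1]. A binomial GLM (logistic
    link) on the mean degree yields the final probability.

    Parameters mirror the common RBF-SVM defaults: ``C = 1`` and the
    median-heuristic-style ``gamma = "scale"``.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale"):
        self.C = C
        self.gamma = gamma

    # -- internal -----------------------------------------------------
    def _pair_probability(self, pair_model, Z: np.ndarray) -> np.ndarray:
        svc, platt = pair_model
        d = svc.decision_function(Z).reshape(-1, 1)
        return platt.predict_proba(d)[:, 1]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_two_classes(y)
        if X.shape[1] < 2:
            raise ValueError("parenclitic networks need >= 2 features")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.pairs_ = list(combinations(range(X.shape[1]), 2))
        self.pair_models_ = {}
        prevalence = float(y.mean())
        for i, j in self.pairs_:
            sub = X[:, [i, j]]
            scaler = StandardScaler().fit(sub)
            Z = scaler.transform(sub)
            try:
                svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma).fit(Z, y)
                d = svc.decision_function(Z).reshape(-1, 1)
                platt = LogisticRegression(C=1e6, max_iter=1000).fit(d, y)
                self.pair_models_[(i, j)] = (scaler, (svc, platt))
            except Exception:  # pragma: no cover - defensive
                log.warning("pair (%d, %d) failed; using prevalence edge", i, j)
                self.pair_models_[(i, j)] = (None, prevalence)
        degrees = self.mean_degree(X)
        glm = sm.GLM(y, sm.add_constant(degrees), family=sm.families.Binomial())
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                # separation is handled below; the warning is expected on
                # strongly separable training folds
                warnings.simplefilter("ignore")
                res = glm.fit(maxiter=200)
            if not np.isfinite(res.params).all():
                raise ValueError("non-finite GLM coefficients")
            self.glm_intercept_ = float(res.params[0])
            self.glm_slope_ = float(res.params[1])
            self.glm_slope_pvalue_ = float(res.pvalues[1])
        except Exception:
            # perfectly separated degrees: fall back to an (effectively
            # unpenalised) logistic fit; the p-value is meaningless then
            log.warning("degree GLM failed (separation?); logistic fallback")
            lr = LogisticRegression(C=1e6, max_iter=5000).fit(
                degrees.reshape(-1, 1), y
            )
            self.glm_intercept_ = float(lr.intercept_[0])
            self.glm_slope_ = float(lr.coef_[0, 0])
            self.glm_slope_pvalue_ = float("nan")
        return self

    def edge_probabilities(self, X) -> np.ndarray:
        """Per-sample edge weights, shape (n_samples, C(p, 2))."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("sample does not cover the model's feature order")
        out = np.empty((X.shape[0], len(self.pairs_)))
        for k, (i, j) in enumerate(self.pairs_):
            scaler, model = self.pair_models_[(i, j)]
            if scaler is None:  # fallback edge
                out[:, k] = model
            else:
                out[:, k] = self._pair_probability(
                    model, scaler.transform(X[:, [i, j]])
                )
        return out

    def mean_degree(self, X) -> np.ndarray:
        """Mean vertex degree per sample, in [0, n_features - 1]."""
        p = self.edge_probabilities(X)
        return 2.0 * p.sum(axis=1) / self.n_features_in_

    def predict_proba(self, X):
        d = self.mean_degree(np.asarray(X, dtype=float))
        eta = self.glm_intercept_ + self.glm_slope_ * d
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_lasso(n_inner_folds: int = 5, random_state: int = 0) -> Pipeline:
    """L1-penalised logistic regression with inner-CV penalty choice.

    Standardisation and penalty selection happen inside ``fit``, i.e.
    on the training fold only, preserving LOOCV validity.
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "lasso",
                LogisticRegressionCV(
                    l1_ratios=(1.0,),  # pure L1
                    solver="liblinear",
                    Cs=np.logspace(-2.5, 2, 12),
                    cv=n_inner_folds,
                    scoring="neg_log_loss",
                    max_iter=2000,
                    random_state=random_state,
                    refit=True,
                    use_legacy_attributes=False,
                ),
            ),
        ]
    )


def lasso_support(model: Pipeline) -> np.ndarray:
    """Indices of features with non-zero coefficients."""
    coef = model.named_steps["lasso"].coef_.ravel()
    return np.flatnonzero(coef != 0.0)


def make_rf(random_state: int = 42) -> RandomForestClassifier:
    """Random forest with the study's settings: 500 trees, depth 10."""
    return RandomForestClassifier(
        n_estimators=500, max_depth=10, random_state=random_state
    )


def get_model(name: str, seed: int = 42):
    """Fresh estimator by model name ('parenclitic' | 'lasso' | 'rf')."""
    if name == "parenclitic":
        return ParencliticClassifier()
    if name == "lasso":
        return make_lasso(random_state=seed)
    if name == "rf":
        return make_rf(random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
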