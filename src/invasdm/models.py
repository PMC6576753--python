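"""Suitability algorithms behind one fit/predict contract, plus the
metric-weighted ensemble.

Five algorithms are exposed as scikit-learn-style estimators (``fit``,
``predict_suitability``, ``get_params``/``set_params``, trailing-underscore
fitted attributes):

* ``GLMSuitability`` — unpenalized logistic regression on linear +
  quadratic terms;
* ``GAMSuitability`` — logistic regression on per-feature cubic B-spline
  bases (univariate smooths, modest basis size);
* ``BRTSuitability`` — gradient-boosted trees, slow learning rate and early
  stopping on an internal holdout;
* ``RFSuitability`` — random forest, class probabilities as suitability;
* ``MaxentSuitability`` — L1-regularized logistic regression on linear +
  quadratic features, the penalized-likelihood formulation equivalent to
  maximum-entropy presence/background modelling (an approximation of the
  Java MaxEnt implementation).

Non-convergence is a first-class outcome: :func:`fit` returns a
:class:`FittedModel` whose status is ``"failed"`` rather than raising, so a
permutation-null engine can count failures instead of crashing.

All estimators sort training rows into a canonical order before fitting, so
predictions are invariant to row permutation of the training data even for
the bootstrap- and subsample-based learners.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import SplineTransformer

from . import evaluate as _evaluate

ALGORITHMS = ("GLM", "GAM", "BRT", "RF", "MAXENT", "ENSEMBLE")

_ALLOWED_KEYS: dict[str, frozenset] = {
    "GLM": frozenset({"degree"}),
    "GAM": frozenset({"n_knots", "degree", "C"}),
    "BRT": frozenset({"learning_rate", "max_depth", "n_estimators"}),
    "RF": frozenset({"n_estimators", "max_features"}),
    "MAXENT": frozenset({"C"}),
    "ENSEMBLE": frozenset({"members", "metrics", "val_fraction"}),
}


class ModelError(ValueError):
    pass


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_Xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1}:
        raise ModelError("y must be binary with both classes present")
    if len(X) != len(y):
        raise ModelError("X and y length mismatch")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ModelError("X contains non-finite values")
    return X, y.astype(int)


def _canonical_order(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Deterministic row order: sort by y then lexicographically by X."""
    keys = [X[c].to_numpy() for c in reversed(list(X.columns))] + [y]
    return np.lexsort(keys)


def _quadratic(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Linear + per-feature quadratic expansion (no cross terms)."""
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    out = np.empty((n, 2 * k))
    out[:, 0::2] = arr
    out[:, 1::2] = arr * arr
    names: list[str] = []
    for c in X.columns:
        names += [str(c), f"{c}^2"]
    return out, names


class _Scaler:
    """Minimal column standardizer (mean 0, sd 1; constant columns left at 0)."""

    def fit(self, Z: np.ndarray) -> "_Scaler":
        self.mean_ = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return (Z - self.mean_) / self.scale_


class SuitabilityModel(BaseEstimator):
    """Common fit/predict surface of all suitability learners."""

    def _check_columns(self, X: pd.DataFrame) -> None:
        got = list(X.columns)
        want = list(self.feature_names_in_)
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            raise ModelError(
                f"column mismatch: missing {missing}, unexpected {extra}"
            )

    def fit(self, X, y):
        X, y = _check_Xy(_as_frame(X), y)
        order = _canonical_order(X, y)
        X = X.iloc[order].reset_index(drop=True)
        y = y[order]
        self.feature_names_in_ = np.array(X.columns, dtype=object)
        self._fit(X, y)
        return self

    def predict_suitability(self, X) -> np.ndarray:
        X = _as_frame(X)
        self._check_columns(X)
        p = self._predict(X)
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    # sklearn compatibility: suitability doubles as P(presence)
    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_suitability(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= 0.5).astype(int)


class GLMSuitability(SuitabilityModel):
    """Logistic GLM with linear + quadratic terms (unpenalized)."""

    def __init__(self, degree: int = 2):
        self.degree = degree

    def _expand(self, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if self.degree == 2:
            return _quadratic(X)
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]

    def _fit(self, X, y):
        Z, names = self._expand(X)
        self.scaler_ = _Scaler().fit(Z)
        self.clf_ = LogisticRegression(C=np.inf, max_iter=5000)
        self.clf_.fit(self.scaler_.transform(Z), y)
        self.expanded_names_ = names

    def _predict(self, X):
        Z, _ = self._expand(X)
        return self.clf_.predict_proba(self.scaler_.transform(Z))[:, 1]

    def export_coefficients(self) -> pd.DataFrame:
        """Coefficients on the standardized feature scale, plus the scaling.

        ``logit(p) = intercept + sum_k coef_k * (z_k - mean_k) / scale_k``
        where ``z_k`` are the expanded (linear + quadratic) features.
        """
        return pd.DataFrame(
            {
                "feature": ["(intercept)"] + self.expanded_names_,
                "coef": np.concatenate([self.clf_.intercept_, self.clf_.coef_[0]]),
                "center": np.concatenate([[0.0], self.scaler_.mean_]),
                "scale": np.concatenate([[1.0], self.scaler_.scale_]),
            }
        )


class MaxentSuitability(SuitabilityModel):
    """L1-penalized logistic regression on linear + quadratic features.

    The penalized-likelihood equivalent of maximum-entropy
    presence/background modelling with linear and quadratic feature classes.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def _fit(self, X, y):
        Z, names = _quadratic(X)
        self.scaler_ = _Scaler().fit(Z)
        self.clf_ = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=self.C, random_state=0, max_iter=2000
        )
        self.clf_.fit(self.scaler_.transform(Z), y)
        self.expanded_names_ = names

    def _predict(self, X):
        Z, _ = _quadratic(X)
        return self.clf_.predict_proba(self.scaler_.transform(Z))[:, 1]

    def export_coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": ["(intercept)"] + self.expanded_names_,
                "coef": np.concatenate([self.clf_.intercept_, self.clf_.coef_[0]]),
                "center": np.concatenate([[0.0], self.scaler_.mean_]),
                "scale": np.concatenate([[1.0], self.scaler_.scale_]),
            }
        )


class GAMSuitability(SuitabilityModel):
    """Logistic additive model: cubic B-spline basis per predictor."""

    def __init__(self, n_knots: int = 5, degree: int = 3, C: float = 1.0):
        self.n_knots = n_knots
        self.degree = degree
        self.C = C

    def _fit(self, X, y):
        self.spline_ = SplineTransformer(
            n_knots=self.n_knots, degree=self.degree, include_bias=False
        ).fit(X)
        Z = self.spline_.transform(X)
        self.clf_ = LogisticRegression(C=self.C, max_iter=5000)
        self.clf_.fit(Z, y)

    def _predict(self, X):
        return self.clf_.predict_proba(self.spline_.transform(X))[:, 1]


class BRTSuitability(SuitabilityModel):
    """Boosted regression trees: slow learning, shallow trees, early stopping."""

    def __init__(
        self,
        learning_rate: float = 0.01,
        max_depth: int = 3,
        n_estimators: int = 1000,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.seed = seed

    def _fit(self, X, y):
        self.clf_ = GradientBoostingClassifier(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            n_iter_no_change=10,
            validation_fraction=0.2,
            random_state=self.seed,
        )
        self.clf_.fit(X.to_numpy(dtype=float), y)

    def _predict(self, X):
        return self.clf_.predict_proba(X.to_numpy(dtype=float))[:, 1]


class RFSuitability(SuitabilityModel):
    """Random forest; suitability = out-of-the-box class probability."""

    def __init__(self, n_estimators: int = 500, max_features: str | float = "sqrt", seed: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.seed = seed

    def _fit(self, X, y):
        self.clf_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.seed,
        )
        self.clf_.fit(X.to_numpy(dtype=float), y)

    def _predict(self, X):
        return self.clf_.predict_proba(X.to_numpy(dtype=float))[:, 1]


class EnsembleSuitability(SuitabilityModel):
    """Convex combination of member predictions, weighted by TSS and AUC.

    Member metrics are measured on an internal validation subset of the
    training rows (seeded stratified split); the weight of member *i* is
    proportional to the mean of its TSS (negative values truncated to 0)
    and AUC there, normalized to sum to 1.  Members that fail to fit get
    weight 0.  Final members are refit on the full training data.
    """

    def __init__(self, members=None, val_fraction: float = 0.2, seed: int = 0):
        self.members = members  # list of (name, estimator) pairs
        self.val_fraction = val_fraction
        self.seed = seed

    @classmethod
    def from_weights(cls, fitted_members, weights) -> "EnsembleSuitability":
        """Ensemble with externally supplied weights over already-fitted members."""
        w = np.asarray(weights, dtype=float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ModelError("weights must be non-negative and sum to 1")
        obj = cls(members=[(f"m{i}", m) for i, m in enumerate(fitted_members)])
        obj.fitted_members_ = list(fitted_members)
        obj.weights_ = w
        obj.member_names_ = [n for n, _ in obj.members]
        obj.feature_names_in_ = fitted_members[0].feature_names_in_
        obj.failed_members_ = []
        return obj

    def _fit(self, X, y):
        if not self.members:
            raise ModelError("ensemble needs at least one member")
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=self.val_fraction, random_state=self.seed
        )
        (train_idx, val_idx), = splitter.split(X, y)
        metrics = []
        fitted = []
        failed = []
        for name, est in self.members:
            try:
                sub = clone(est).fit(X.iloc[train_idx], y[train_idx])
                s_tr = sub.predict_suitability(X.iloc[train_idx])
                s_val = sub.predict_suitability(X.iloc[val_idx])
                thr = _evaluate.best_threshold(y[train_idx], s_tr)
                t = max(_evaluate.tss(y[val_idx], s_val, thr).tss, 0.0)
                a = _evaluate.auc(y[val_idx], s_val)
                full = clone(est).fit(X, y)
                metrics.append(0.5 * (t + a))
                fitted.append(full)
                failed.append(False)
            except Exception as exc:  # member failure gets weight 0
                metrics.append(0.0)
                fitted.append(None)
                failed.append(True)
        ok = [i for i, f in enumerate(failed) if not f]
        if not ok:
            raise ModelError("all ensemble members failed to fit")
        w = np.zeros(len(self.members))
        total = sum(metrics[i] for i in ok)
        if total > 0:
            for i in ok:
                w[i] = metrics[i] / total
        else:
            for i in ok:
                w[i] = 1.0 / len(ok)
        self.weights_ = w
        self.fitted_members_ = fitted
        self.member_names_ = [n for n, _ in self.members]
        self.member_metrics_ = metrics
        self.failed_members_ = [self.member_names_[i] for i, f in enumerate(failed) if f]

    def _predict(self, X):
        p = np.zeros(len(X))
        for w, m in zip(self.weights_, self.fitted_members_):
            if w > 0 and m is not None:
                p += w * m.predict_suitability(X)
        return p


# ---------------------------------------------------------------------------
# Spec-driven construction and the fit/predict wrappers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Algorithm name, hyperparameters (closed key set), and seed."""

    algorithm: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self):
        algo = self.algorithm.upper()
        object.__setattr__(self, "algorithm", algo)
        if algo not in ALGORITHMS:
            raise ModelError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
        params = dict(self.hyperparameters)
        unknown = set(params) - _ALLOWED_KEYS[algo]
        if unknown:
            raise ModelError(
                f"{algo}: unknown hyperparameters {sorted(unknown)}; "
                f"allowed: {sorted(_ALLOWED_KEYS[algo])}"
            )
        object.__setattr__(self, "hyperparameters", tuple(sorted(params.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def build_estimator(spec: ModelSpec) -> SuitabilityModel:
    p = spec.params
    if spec.algorithm == "GLM":
        return GLMSuitability(**p)
    if spec.algorithm == "GAM":
        return GAMSuitability(**p)
    if spec.algorithm == "BRT":
        return BRTSuitability(seed=spec.seed, **p)
    if spec.algorithm == "RF":
        return RFSuitability(seed=spec.seed, **p)
    if spec.algorithm == "MAXENT":
        return MaxentSuitability(**p)
    if spec.algorithm == "ENSEMBLE":
        members = p.pop("members", None)
        if members is None:
            member_specs = [ModelSpec(a, seed=spec.seed) for a in ("GLM", "GAM", "BRT", "RF", "MAXENT")]
        else:
            member_specs = [m if isinstance(m, ModelSpec) else ModelSpec(m, seed=spec.seed) for m in members]
        pairs = [(m.algorithm, build_estimator(m)) for m in member_specs]
        return EnsembleSuitability(members=pairs, seed=spec.seed, **{k: v for k, v in p.items() if k == "val_fraction"})
    raise ModelError(spec.algorithm)


@dataclasses.dataclass
class FittedModel:
    """A model or its recorded failure."""

    spec: ModelSpec
    estimator: SuitabilityModel | None
    columns: list[str]
    status: str  # "ok" | "failed"
    failure_reason: str = ""


def fit(spec: ModelSpec, X, y) -> FittedModel:
    """Fit the spec'd algorithm; non-convergence is recorded, not raised."""
    X = _as_frame(X)
    _check_Xy(X, y)  # single-class y is a caller error, raised before fitting
    est = build_estimator(spec)
    try:
        est.fit(X, y)
        p = est.predict_suitability(X)
        if not np.isfinite(p).all():
            raise ModelError("non-finite predictions on training data")
        return FittedModel(spec, est, list(X.columns), "ok")
    except ModelError:
        raise
    except Exception as exc:
        return FittedModel(spec, None, list(X.columns), "failed", failure_reason=str(exc))


def predict(model: FittedModel, X) -> np.ndarray:
    """Suitability scores in [0, 1]; refuses failed models and column drift."""
    if model.status != "ok":
        raise ModelError(f"cannot predict from a failed model ({model.failure_reason})")
    return model.estimator.predict_suitability(_as_frame(X))


def fit_ensemble(member_specs: Sequence[ModelSpec], X, y, seed: int = 0) -> FittedModel:
    """Fit the metric-weighted ensemble over the given member algorithms."""
    spec = ModelSpec("ENSEMBLE", (("members", tuple(member_specs)),), seed=seed)
    return fit(spec, X, y)
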