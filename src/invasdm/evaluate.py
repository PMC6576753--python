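"""TSS/AUC accuracy statistics, permutation null models, and effect sizes.

A model's headline accuracy can be inflated by spatial sorting bias and
pseudo-absence artefacts, so raw TSS > 0 or AUC > 0.5 is not evidence of
skill.  The null-model engine refits the identical model on
predictor-permuted data — the same response vector, the same train/test
membership, but the rows of the predictor matrix randomly re-assigned to
observations — and summarizes the resulting statistic distribution by its
97.5th percentile.  The *effect size* of a real model is its statistic
minus that percentile; only strictly positive effect sizes indicate
performance better than chance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class EvaluationError(ValueError):
    pass


def _check_binary(obs) -> np.ndarray:
    obs = np.asarray(obs).astype(int)
    if set(np.unique(obs)) != {0, 1}:
        raise EvaluationError("observations must contain both classes")
    return obs


# ---------------------------------------------------------------------------
# Accuracy statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TssResult:
    tss: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def tss(obs, scores, threshold: float) -> TssResult:
    """True Skill Statistic at a fixed binarization threshold.

    Scores at or above the threshold predict presence.  TSS = sensitivity +
    specificity - 1, in [-1, 1].
    """
    obs = _check_binary(obs)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (obs == 1)))
    fp = int(np.sum(pred & (obs == 0)))
    tn = int(np.sum(~pred & (obs == 0)))
    fn = int(np.sum(~pred & (obs == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return TssResult(sens + spec - 1.0, sens, spec, tp, fp, tn, fn)


def auc(obs, scores) -> float:
    """Probability a random presence outscores a random absence (ties 1/2).

    Rank (Mann-Whitney) formulation of the area under the ROC curve.
    """
    obs = _check_binary(obs)
    scores = np.asarray(scores, dtype=float)
    r = rankdata(scores)
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    return float((r[obs == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def best_threshold(obs, scores) -> float:
    """Threshold maximizing TSS; ties resolved toward the smallest threshold.

    Chosen on *training* predictions and then frozen for testing, so the
    binarization rule never sees the test data.
    """
    obs = _check_binary(obs)
    scores = np.asarray(scores, dtype=float)
    # sens/spec at every candidate threshold via cumulative counts over the
    # descending-sorted unique scores (prediction rule: score >= threshold)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = obs[order]
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]  # last row of each tie block
    tp = np.cumsum(y_sorted)[boundary]
    fp = np.cumsum(1 - y_sorted)[boundary]
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    tss_vals = tp / n1 - fp / n0  # sens + spec - 1
    thresholds = s_sorted[boundary]
    best = np.flatnonzero(tss_vals == tss_vals.max())[-1]  # lowest threshold wins ties
    return float(thresholds[best])


@dataclasses.dataclass
class EvalResult:
    """Real-model accuracy at the frozen training threshold."""

    tss: float
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.tss <= 1.0 + 1e-9:
            raise EvaluationError(f"TSS out of range: {self.tss}")
        if not 0.0 <= self.auc <= 1.0:
            raise EvaluationError(f"AUC out of range: {self.auc}")


def evaluate_scores(y_train, s_train, y_test, s_test) -> EvalResult:
    """Pick the TSS-maximizing threshold on training scores, evaluate on test."""
    thr = best_threshold(y_train, s_train)
    t = tss(y_test, s_test, thr)
    a = auc(y_test, s_test)
    return EvalResult(t.tss, a, thr, t.tp, t.fp, t.tn, t.fn)


# ---------------------------------------------------------------------------
# Permutation null models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray
    n_failed: int = 0

    @property
    def percentile_97_5(self) -> float:
        """97.5th percentile, linear interpolation between order statistics."""
        return float(np.percentile(self.values, 97.5))


def null_distribution(
    spec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
    mode: str = "joint",
    max_fail_frac: float = 0.5,
) -> dict[str, NullDistribution]:
    """Refit and re-evaluate the model on ``n_null`` predictor permutations.

    Each permutation re-assigns the rows of the combined (train + test)
    predictor matrix to response rows at random; the response vector and the
    train/test membership stay fixed, and the permuted model is fit,
    thresholded, and evaluated exactly like the real one.  ``mode="joint"``
    permutes whole rows (preserving inter-predictor correlation);
    ``mode="per_column"`` permutes every column independently.

    Fit failures are excluded from the distribution and counted; more than
    ``max_fail_frac`` failures voids the distribution (the recorded fate of
    boosted-tree null models in practice).
    """
    from . import models as _models  # local import; models imports this module

    if n_null < 1:
        raise EvaluationError("n_null must be >= 1")
    if mode not in ("joint", "per_column"):
        raise EvaluationError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    X_all = pd.concat([X_train, X_test], ignore_index=True)
    columns = list(X_all.columns)
    arr = X_all.to_numpy(dtype=float)
    n_tr = len(X_train)
    n_all = len(arr)
    tss_vals: list[float] = []
    auc_vals: list[float] = []
    n_failed = 0
    for _ in range(n_null):
        if mode == "joint":
            ap = arr[rng.permutation(n_all)]
        else:
            ap = np.column_stack([arr[rng.permutation(n_all), j] for j in range(arr.shape[1])])
        Xp = pd.DataFrame(ap, columns=columns)
        fm = _models.fit(spec, Xp.iloc[:n_tr], y_train)
        if fm.status != "ok":
            n_failed += 1
            continue
        s_tr = _models.predict(fm, Xp.iloc[:n_tr])
        s_te = _models.predict(fm, Xp.iloc[n_tr:].reset_index(drop=True))
        res = evaluate_scores(y_train, s_tr, y_test, s_te)
        tss_vals.append(res.tss)
        auc_vals.append(res.auc)
    if n_failed > max_fail_frac * n_null:
        raise EvaluationError(
            f"{n_failed}/{n_null} null fits failed; null distribution untrustworthy"
        )
    return {
        "TSS": NullDistribution("TSS", np.asarray(tss_vals), n_failed),
        "AUC": NullDistribution("AUC", np.asarray(auc_vals), n_failed),
    }


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EffectSize:
    """Real statistic minus the null 97.5th percentile, per statistic.

    Positive values mean the model performed better than its null models;
    negative values mean no better than chance, however high the raw
    statistic.
    """

    tss_es: float
    auc_es: float
    tss_null_97_5: float
    auc_null_97_5: float
    tss_better_than_null: bool = dataclasses.field(init=False)
    auc_better_than_null: bool = dataclasses.field(init=False)

    def __post_init__(self):
        self.tss_better_than_null = self.tss_es > 0
        self.auc_better_than_null = self.auc_es > 0


def effect_sizes(real: EvalResult, nulls: dict[str, NullDistribution]) -> EffectSize:
    for key in ("TSS", "AUC"):
        if key not in nulls:
            raise EvaluationError(f"missing null distribution for {key}")
    t_null = nulls["TSS"].percentile_97_5
    a_null = nulls["AUC"].percentile_97_5
    return EffectSize(real.tss - t_null, real.auc - a_null, t_null, a_null)


def results_frame(rows: list[dict]) -> pd.DataFrame:
    """Long-format results table: one row per species x scenario x algorithm."""
    cols = [
        "species", "scenario", "algorithm", "status",
        "TSS_real", "AUC_real", "threshold",
        "TSSnull_97_5", "AUCnull_97_5", "TSSes", "AUCes",
        "TSS_better_than_null", "AUC_better_than_null", "n_null_failed",
    ]
    return pd.DataFrame(rows, columns=cols)
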