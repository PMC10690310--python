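"""Task metrics and bootstrap statistics.

Binary tasks are scored by ROC AUC and PR AUC (average precision); regression
by R^2 (which may be negative). Uncertainty comes from a standard bootstrap:
B = 1000 resamples of the n test predictions drawn with replacement, one
score per resample, and a 90% CI read off the 50th and 950th ranked scores.
Model comparisons use a two-sided paired t-test on the differences between
sampled-set corresponding scores — resample index streams are a pure
function of (n, seed), so two models evaluated with the same seed on the
same test set are scored on identical resamples — with significance declared
below a Bonferroni-corrected 1e-3 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, r2_score, roc_auc_score


@dataclass
class PredictionSet:
    ids: list
    y_true: np.ndarray
    y_score: np.ndarray
    task: str  # binary | regression

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=np.float64)
        self.y_score = np.asarray(self.y_score, dtype=np.float64)
        if len(self.ids) != len(self.y_true) or len(self.y_true) != len(self.y_score):
            raise ValueError("ids, y_true and y_score must have equal lengths")
        if self.task == "binary" and not set(np.unique(self.y_true)) <= {0.0, 1.0}:
            raise ValueError("binary y_true must contain only 0/1")

    def __len__(self):
        return len(self.y_true)


@dataclass
class BootstrapResult:
    metric: str
    point_estimate: float
    scores: np.ndarray
    level: float
    ci: tuple
    B: int
    seed: int


class MetricError(ValueError):
    pass


def compute_metric(preds: PredictionSet, metric: str) -> float:
    """roc_auc (ties get half credit), pr_auc (average precision), or r2."""
    y, s = preds.y_true, preds.y_score
    if metric in ("roc_auc", "pr_auc"):
        if len(np.unique(y)) < 2:
            raise MetricError(f"{metric} undefined with a single class")
        if metric == "roc_auc":
            return float(roc_auc_score(y, s))
        return float(average_precision_score(y, s))
    if metric == "r2":
        if len(y) < 2 or np.var(y) == 0:
            raise MetricError("r2 needs >= 2 samples with nonzero target variance")
        return float(r2_score(y, s))
    raise ValueError(f"unknown metric {metric!r}")


def _metric_on_arrays(y: np.ndarray, s: np.ndarray, metric: str) -> float:
    if metric == "roc_auc":
        return float(roc_auc_score(y, s))
    if metric == "pr_auc":
        return float(average_precision_score(y, s))
    return float(r2_score(y, s))


def _metric_degenerate(y_sub: np.ndarray, metric: str) -> bool:
    if metric in ("roc_auc", "pr_auc"):
        return len(np.unique(y_sub)) < 2
    return np.var(y_sub) == 0


def _auc_rows(y_rows: np.ndarray, s_rows: np.ndarray) -> np.ndarray:
    """Row-wise ROC AUC via the rank (Mann-Whitney) identity, ties half."""
    ranks = stats.rankdata(s_rows, axis=1, method="average")
    pos = y_rows == 1
    npos = pos.sum(axis=1)
    nneg = y_rows.shape[1] - npos
    rank_sum = (ranks * pos).sum(axis=1)
    return (rank_sum - npos * (npos + 1) / 2.0) / (npos * nneg)


def bootstrap_scores(preds: PredictionSet, metric: str, B: int = 1000,
                     seed: int = 0, max_redraws: int = 50) -> BootstrapResult:
    """B resamples of size n with replacement; degenerate resamples redrawn.

    The index stream depends only on (n, seed) and on which resamples were
    degenerate — a function of y_true alone — so two models scored on the
    same test set with the same seed see identical resamples and their
    per-iteration scores pair up.
    """
    n = len(preds)
    if n < 2:
        raise ValueError("need at least 2 predictions to bootstrap")
    rng = np.random.default_rng(seed)
    y, s = preds.y_true, preds.y_score
    idx = rng.integers(0, n, size=(B, n))
    for attempt in range(max_redraws + 1):
        bad = np.array([_metric_degenerate(y[row], metric) for row in idx])
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:
        raise MetricError(
            f"metric {metric} undefined on {max_redraws} consecutive redraws")
    if metric == "roc_auc":
        scores = _auc_rows(y[idx], s[idx])
    elif metric == "r2":
        yt, sp = y[idx], s[idx]
        sse = ((yt - sp) ** 2).sum(axis=1)
        sst = ((yt - yt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        scores = 1.0 - sse / sst
    else:
        scores = np.array([_metric_on_arrays(y[row], s[row], metric)
                           for row in idx])
    point = compute_metric(preds, metric)
    ci = ci_from_scores(scores, 0.9)
    return BootstrapResult(metric=metric, point_estimate=point, scores=scores,
                           level=0.9, ci=ci, B=B, seed=seed)


def ci_from_scores(scores, level: float = 0.9) -> tuple:
    """Rank-based CI: for B=1000 and level 0.9, ranks 50 and 950 (1-based)."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    scores = np.sort(np.asarray(scores, dtype=np.float64))
    B = len(scores)
    if B < 20:
        raise ValueError("need at least 20 scores")
    r = max(1, math.ceil(B * (1.0 - level) / 2.0))
    return (float(scores[r - 1]), float(scores[B - r - 1]))


def paired_bootstrap_test(scores_a, scores_b) -> float:
    """Two-sided one-sample t-test on paired score differences (H0: mean 0)."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    d = a - b
    # differences that are constant to machine precision short-circuit scipy
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, float(np.abs(np.mean(d)))):
        return 1.0 if np.mean(d) == 0.0 else 0.0
    res = stats.ttest_1samp(d, 0.0)
    return float(res.pvalue)


def bonferroni_adjust(p_values, alpha: float = 1e-3) -> list:
    """Flag i true iff p_i < alpha / m for m hypotheses."""
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p-value list")
    if any(not (0.0 <= p <= 1.0) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_values)
    return [p < alpha / m for p in p_values]


def evaluate_predictions(preds: PredictionSet, B: int = 1000, seed: int = 0) -> dict:
    """Score a prediction set with its task's metrics + bootstrap CIs."""
    metrics = ("roc_auc", "pr_auc") if preds.task == "binary" else ("r2",)
    out = {}
    for m in metrics:
        out[m] = bootstrap_scores(preds, m, B=B, seed=seed)
    return out
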