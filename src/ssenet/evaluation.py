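"""Prediction-error and classification metrics, k-fold CV, grid selection.

Model selection follows the deviance-minimizing protocol: every admissible
(s0, s1) pair is evaluated with identical stratified fold assignments and the
pair with the smallest mean cross-validated deviance is chosen (ties broken by
smaller s0, then smaller s1).  Classification metrics are computed on pooled
held-out predictions per repeat (micro-averaged), then averaged over repeats.
Undefined metrics (zero denominators) propagate as NaN and are excluded from
averages, with missing counts reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .em_solver import DesignData, FitControl, fit_ssen, predict_prob
from .spatial_graph import AdjacencyGraph
from .ssen_prior import PriorSpec

logger = logging.getLogger(__name__)

PREDICTION_METRICS = ("deviance", "auc", "mse", "mae", "mc")
CLASSIFICATION_METRICS = ("ac", "sn", "sp", "ppv", "npv", "mcc", "f1")
ALL_METRICS = PREDICTION_METRICS + CLASSIFICATION_METRICS

#: metrics for which smaller is better
LOWER_IS_BETTER = frozenset({"deviance", "mse", "mae", "mc"})

_P_CLIP = 1e-10


def binomial_deviance(y, p_hat) -> float:
    """Total binomial deviance -2 sum[y log p + (1-y) log(1-p)].

    Predicted probabilities are clipped away from 0/1 before taking logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p_hat must have equal length")
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def auc_score(y, p_hat) -> float:
    """Mann-Whitney AUC (ties count 1/2); NaN if only one class is present."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def prediction_error_metrics(y, p_hat) -> dict:
    """Deviance, AUC, MSE, MAE and misclassification of predicted probabilities.

    Misclassification uses the strict rule mean[|y_i - p_i| > 0.5], so a
    prediction of exactly 0.5 never counts as misclassified.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p_hat must have equal length")
    return {
        "deviance": binomial_deviance(y, p),
        "auc": auc_score(y, p),
        "mse": float(np.mean((y - p) ** 2)),
        "mae": float(np.mean(np.abs(y - p))),
        "mc": float(np.mean(np.abs(y - p) > 0.5)),
    }


def classify(p_hat, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff p_hat > threshold (strict); threshold must lie in (0, 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    return (np.asarray(p_hat, dtype=float) > threshold).astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV, MCC and F1.

    Any metric with a zero denominator is returned as NaN; the MCC is NaN
    whenever any of its four marginal factors is zero.
    """
    if c.total == 0:
        raise ValueError("confusion table is empty")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    f1_den = 2 * tp + fp + fn
    factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(factors) if factors > 0 else float("nan")
    return {
        "ac": (tp + tn) / c.total,
        "sn": ratio(tp, tp + fn),
        "sp": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "mcc": float(mcc),
        "f1": ratio(2 * tp, f1_den),
    }


def stratified_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Outcome-stratified fold assignment from a seeded shuffle."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k}; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class CVResult:
    """Held-out predictions and pooled metrics from (repeated) k-fold CV."""

    predictions: np.ndarray  # (repeats, N) held-out probabilities
    fold_ids: np.ndarray  # (repeats, N) fold index of each subject
    per_repeat: pd.DataFrame  # one row of metrics per repeat
    metrics: dict  # metric -> mean over repeats (NaN-aware)
    missing: dict  # metric -> number of repeats where undefined


def _pooled_metrics(y, p_hat, threshold=0.5) -> dict:
    out = prediction_error_metrics(y, p_hat)
    labels = classify(p_hat, threshold)
    out.update(confusion_metrics(ConfusionCounts.from_labels(y, labels)))
    return out


def kfold_cv(
    data: DesignData,
    prior: PriorSpec,
    graph: AdjacencyGraph | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    control: FitControl | None = None,
    folds_per_repeat: list | None = None,
) -> CVResult:
    """Stratified k-fold CV, optionally repeated with reshuffled folds.

    Every subject receives exactly one held-out prediction per repeat;
    metrics are computed on the pooled held-out predictions of each repeat and
    then averaged across repeats.  Fold assignments may be passed explicitly
    (``folds_per_repeat``) so several models or grid points can share them.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = data.y.astype(int)
    n = data.n_subjects
    if folds_per_repeat is None:
        folds_per_repeat = [stratified_folds(y, k, seed + r) for r in range(repeats)]
    repeats = len(folds_per_repeat)
    preds = np.full((repeats, n), np.nan)
    fold_ids = np.full((repeats, n), -1, dtype=int)
    for r, folds in enumerate(folds_per_repeat):
        for f, (train, test) in enumerate(folds):
            fit = fit_ssen(data.subset(train), prior, graph, control)
            preds[r, test] = predict_prob(fit, data.X[test])
            fold_ids[r, test] = f
    rows = [_pooled_metrics(y, preds[r]) for r in range(repeats)]
    per_repeat = pd.DataFrame(rows)
    metrics = {
        m: (float(np.nanmean(col)) if col.notna().any() else float("nan"))
        for m in ALL_METRICS
        for col in (per_repeat[m],)
    }
    missing = {m: int(per_repeat[m].isna().sum()) for m in ALL_METRICS}
    return CVResult(preds, fold_ids, per_repeat, metrics, missing)


@dataclass
class CVReport:
    """Grid-search record: one metrics row per admissible (s0, s1) point."""

    records: pd.DataFrame
    chosen: tuple[float, float]
    predictions: dict  # (s0, s1) -> (repeats, N) held-out probabilities

    @property
    def chosen_row(self) -> pd.Series:
        s0, s1 = self.chosen
        m = (self.records["s0"] == s0) & (self.records["s1"] == s1)
        return self.records[m].iloc[0]


def _choose_best(records: pd.DataFrame) -> tuple[float, float]:
    """Argmin of CV deviance; ties broken by smaller s0, then smaller s1."""
    ordered = records.sort_values(["deviance", "s0", "s1"], kind="mergesort")
    top = ordered.iloc[0]
    return float(top["s0"]), float(top["s1"])


def grid_select(
    data: DesignData,
    prior_template: PriorSpec,
    graph: AdjacencyGraph | None = None,
    s0_grid=(0.05, 0.1),
    s1_grid=(1.0, 2.0),
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    control: FitControl | None = None,
) -> CVReport:
    """Deviance-minimizing search over the (s0, s1) grid with shared folds.

    Pairs with s0 >= s1 are inadmissible and skipped with a logged notice.
    """
    pairs = [
        (float(s0), float(s1)) for s0 in s0_grid for s1 in s1_grid if s0 < s1
    ]
    n_skipped = len(list(s0_grid)) * len(list(s1_grid)) - len(pairs)
    if n_skipped:
        logger.info("skipped %d inadmissible grid pairs (s0 >= s1)", n_skipped)
    if not pairs:
        raise ValueError("no admissible (s0, s1) pairs with s0 < s1 in the grid")
    folds = [stratified_folds(data.y.astype(int), k, seed + r) for r in range(repeats)]
    rows, predictions = [], {}
    for s0, s1 in pairs:
        prior = replace(prior_template, s0=s0, s1=s1)
        res = kfold_cv(
            data, prior, graph, k=k, control=control, folds_per_repeat=folds
        )
        rows.append({"s0": s0, "s1": s1, **res.metrics})
        predictions[(s0, s1)] = res.predictions
    records = pd.DataFrame(rows)
    return CVReport(records=records, chosen=_choose_best(records), predictions=predictions)


def path_select(
    data: DesignData,
    xi: float,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    control: FitControl | None = None,
    n_points: int = 100,
    ratio: float = 0.001,
) -> CVReport:
    """Automatic penalty-path selection for the traditional lasso/EN.

    Builds a 100-point log-spaced path of penalty multipliers from nu_max (the
    smallest multiplier that zeroes every coefficient at the null fit) down to
    ``ratio * nu_max`` and picks the scale minimizing CV deviance.  The scale
    is reported as s0 = s1 = 1/nu.
    """
    Xs = data.standardized()
    y = data.y
    score = np.abs(Xs.T @ (y - y.mean()))
    nu_max = float(score.max()) / max(xi, 1e-3)
    nus = np.geomspace(nu_max, ratio * nu_max, n_points)
    folds = [stratified_folds(y.astype(int), k, seed + r) for r in range(repeats)]
    rows, predictions = [], {}
    for nu in nus:
        s = 1.0 / nu
        prior = PriorSpec(xi=xi, s0=s, s1=s, spike_slab=False)
        res = kfold_cv(data, prior, None, k=k, control=control, folds_per_repeat=folds)
        rows.append({"s0": s, "s1": s, **res.metrics})
        predictions[(s, s)] = res.predictions
    records = pd.DataFrame(rows)
    return CVReport(records=records, chosen=_choose_best(records), predictions=predictions)
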