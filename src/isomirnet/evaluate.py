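"""Classification metrics and cross-validation.

AUROC is computed with the rank statistic (midranks for ties), AUPR as
the interpolation-free sum of precision over recall increments. Undefined
ratios (zero denominators) are reported as NaN with a warning, never
silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError, UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    f1: float
    precision: float
    recall: float
    specificity: float
    n_pos: int
    n_neg: int


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return num / den


def confusion_metrics(labels, predictions) -> dict[str, float]:
    """Precision, recall, specificity and F1 from binary predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise DataError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1") \
        if np.isfinite(precision) and np.isfinite(recall) else float("nan")
    return {"precision": precision, "recall": recall,
            "specificity": specificity, "f1": f1}


def ranking_metrics(labels, scores) -> dict[str, float]:
    """AUROC (midrank statistic) and AUPR (stepwise precision summation)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise DataError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ranking metrics need both classes present")
    ranks = rankdata(s)  # midranks for ties
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # AUPR: walk thresholds from the highest score down; each positive
    # contributes the precision at its recall increment (ties processed as
    # one block at the block's precision).
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = fp = 0
    aupr = 0.0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp_block = int(y_sorted[i:j].sum())
        fp_block = (j - i) - tp_block
        tp += tp_block
        fp += fp_block
        if tp_block:
            aupr += tp_block / n_pos * (tp / (tp + fp))
        i = j
    return {"auroc": float(auroc), "aupr": float(aupr)}


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricReport:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    rank = ranking_metrics(y, s)
    conf = confusion_metrics(y, (s >= threshold).astype(int))
    return MetricReport(
        auroc=rank["auroc"], aupr=rank["aupr"], f1=conf["f1"],
        precision=conf["precision"], recall=conf["recall"],
        specificity=conf["specificity"],
        n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
    )


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Label-stratified fold assignment (0..n_folds-1) per sample."""
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


def cross_validate(
    pairs: pd.DataFrame,
    config,
    n_folds: int = 10,
    seed: int = 0,
    epochs: int | None = None,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the interaction model.

    Trains one model per fold on the remaining folds and reports per-fold
    metrics plus the mean row.
    """
    from .model import build_model

    folds = stratified_folds(pairs["label"].to_numpy(), n_folds, seed)
    rows = []
    for k in range(n_folds):
        train = pairs[folds != k].reset_index(drop=True)
        test = pairs[folds == k].reset_index(drop=True)
        predictor = build_model(config)
        predictor.fit(train, epochs=epochs)
        prob = predictor.predict_proba(test)
        report = evaluate_predictions(
            test["label"].to_numpy(), prob, config.decision_threshold
        )
        rows.append({"fold": k, **report.__dict__})
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean(numeric_only=True)
    mean["fold"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)
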