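"""Binary-classification metrics and stratified k-fold cross-validation.

Six metrics summarize a fold: accuracy, sensitivity, specificity, precision,
the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the area under the ROC curve.  Threshold metrics use a fixed 0.5 cutoff
(score >= 0.5 predicts positive); any metric with a zero denominator is
reported as NaN rather than raising.  Cross-validation trains the full
ensemble on k-1 folds and scores the held-out fold, then reports per-fold
metrics with their mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import RPIDataset, stratified_kfold
from .model import ModuleConfig, PairFeatures, predict, train_ensemble

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "sn", "sp", "pre", "mcc", "auc")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    pre: float
    mcc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(labels: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a score threshold (score >= threshold => positive)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluationError(
            f"labels and scores length mismatch: {labels.shape} vs {scores.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise EvaluationError("labels must be 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve; ties grouped; NaN if one class."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return math.nan
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def metric_set(counts: ConfusionCounts, labels: Sequence[int] | None = None,
               scores: Sequence[float] | None = None) -> MetricSet:
    """The six metrics from confusion counts (AUC needs labels and scores)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    auc = math.nan
    if labels is not None and scores is not None:
        auc = roc_auc(labels, scores)
    return MetricSet(
        acc=_ratio(tp + tn, counts.total),
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        pre=_ratio(tp, tp + fp),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den else math.nan,
        auc=auc,
    )


def evaluate(labels: Sequence[int], scores: Sequence[float],
             threshold: float = 0.5) -> MetricSet:
    """Convenience: confusion + metric_set in one call."""
    return metric_set(confusion(labels, scores, threshold), labels, scores)


@dataclass
class CVResult:
    folds: list[MetricSet]
    k: int
    seed: int
    means: dict[str, float] = field(init=False)
    stds: dict[str, float] = field(init=False)

    def __post_init__(self):
        table = {name: np.array([getattr(f, name) for f in self.folds])
                 for name in METRIC_NAMES}
        self.means = {name: float(np.mean(v)) for name, v in table.items()}
        # sample standard deviation across folds
        self.stds = {name: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
                     for name, v in table.items()}

    def summary(self) -> pd.DataFrame:
        rows = [{"fold": i, **f.as_dict()} for i, f in enumerate(self.folds)]
        rows.append({"fold": "mean", **self.means})
        rows.append({"fold": "sd", **self.stds})
        return pd.DataFrame(rows).set_index("fold")


def permute_labels(dataset: RPIDataset, seed: int = 0) -> RPIDataset:
    """Return a copy of the dataset with pair labels randomly permuted.

    Breaks any sequence-label association while preserving class balance;
    useful as a negative control for learnability claims.
    """
    from .dataset import InteractionPair

    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in dataset.pairs])
    rng.shuffle(labels)
    pairs = [InteractionPair(p.rna_id, p.protein_id, int(l))
             for p, l in zip(dataset.pairs, labels)]
    return dataset.with_pairs(pairs)


def cross_validate(dataset: RPIDataset, config: ModuleConfig = ModuleConfig(),
                   k: int = 5, seed: int = 0,
                   features: PairFeatures | None = None) -> CVResult:
    """Stratified k-fold CV of the full ensemble; no train/test overlap.

    Features are per-sequence functions (no fitting), so they are encoded
    once for the whole dataset; model training only ever sees the k-1
    training folds.
    """
    folds = stratified_kfold(dataset.pairs, k=k, seed=seed)
    if features is None:
        features = PairFeatures.from_dataset(dataset)
    results = []
    for i, test_pairs in enumerate(folds):
        test_keys = {p.key for p in test_pairs}
        train_pairs = [p for p in dataset.pairs if p.key not in test_keys]
        train_ds = dataset.with_pairs(train_pairs)
        model, _ = train_ensemble(train_ds, config, features=features)
        scores = predict(model, test_pairs, features)
        labels = [p.label for p in test_pairs]
        fold_metrics = evaluate(labels, scores)
        logger.info("fold %d/%d: %s", i + 1, k,
                    {n: round(v, 4) for n, v in fold_metrics.as_dict().items()})
        results.append(fold_metrics)
    return CVResult(results, k=k, seed=seed)
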