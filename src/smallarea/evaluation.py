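"""Cross-validated evaluation of risk models: confusion matrix, AUC.

Evaluation follows the standard prediction-model protocol: stratified
10-fold cross-validation, with the unbalanced-data correction performed
inside each training split only; predictions are pooled across folds into
one confusion matrix at the 0.5 probability cutoff, and the AUC is the
Mann-Whitney rank statistic on the pooled predicted probabilities.
Positive = high risk = uniqueness above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import FittingError, ParameterError, UndefinedResultError
from .risk_model import LogitRiskModel, fit_downsampled, fit_kz

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "auc",
    "sensitivity_specificity",
    "confusion_matrix_at_cutoff",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """(tp/(tp+fn), tn/(tn+fp)); positives are high-risk observations."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedResultError("sensitivity/specificity need both classes present")
    return cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a randomly chosen positive (above-threshold)
    observation receives a higher score than a randomly chosen negative one,
    with ties counted half (midranks).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ParameterError("scores and labels must be equal-length 1-d sequences")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedResultError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_matrix_at_cutoff(
    labels: Sequence[int], probs: Sequence[float], cutoff: float = 0.5
) -> ConfusionMatrix:
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(probs, dtype=float) > cutoff).astype(int)
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


@dataclass
class EvalReport:
    """Pooled cross-validation result for one threshold model."""

    auc: float
    sensitivity: float
    specificity: float
    confusion: ConfusionMatrix
    folds: list[dict] = field(default_factory=list)
    seed: int | None = None
    k: int = 10
    method: str = "downsample"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
            },
            "folds": self.folds,
            "seed": self.seed,
            "k": self.k,
            "method": self.method,
        }


_METHODS: dict[str, Callable] = {
    "downsample": lambda df, resp, seed: fit_downsampled(df, resp, seed),
    "kz": lambda df, resp, seed: fit_kz(df, resp),
}


def cross_validate(
    data: pd.DataFrame,
    response: str,
    method: str = "downsample",
    k: int = 10,
    seed: int = 0,
    cutoff: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of a threshold model.

    ``data`` needs columns ``pop``, ``max_combs`` and the response
    (``I05`` or ``I20``).  The unbalanced-data correction (and the scaler)
    is recomputed inside each training split; every observation is predicted
    exactly once and predictions are pooled before computing the confusion
    matrix (at ``cutoff``) and the AUC.  Bit-reproducible for a fixed seed.
    """
    if method not in _METHODS:
        raise ParameterError(f"unknown fit method {method!r}")
    y = data[response].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise FittingError(
            f"stratified {k}-fold CV needs >= {k} rows per class, have {counts}"
        )
    pop = data["pop"].to_numpy(dtype=float)
    mc = data["max_combs"].to_numpy(dtype=float)

    probs = np.full(len(y), np.nan)
    folds_meta: list[dict] = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(skf.split(pop, y)):
        train_df = pd.DataFrame(
            {"pop": pop[train], "max_combs": mc[train], response: y[train]}
        )
        model: LogitRiskModel = _METHODS[method](train_df, response, seed + fold)
        probs[test] = model.predict_probability(pop[test], mc[test])
        folds_meta.append(
            {
                "fold": fold,
                "n_train": int(len(train)),
                "n_test": int(len(test)),
                "coefficients": list(model.coefficients),
                "warning": model.warning,
            }
        )
    assert not np.isnan(probs).any()

    cm = confusion_matrix_at_cutoff(y, probs, cutoff)
    sens, spec = sensitivity_specificity(cm)
    return EvalReport(
        auc=auc(probs, y),
        sensitivity=sens,
        specificity=spec,
        confusion=cm,
        folds=folds_meta,
        seed=seed,
        k=k,
        method=method,
    )
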