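"""ROC/PRC evaluation under a controlled negative excess.

AUROC equals the probability that a random positive outscores a random
negative (ties counted half).  AUPRC uses the step estimator (summing
precision at each recall increment) rather than trapezoidal interpolation,
which is biased for precision-recall curves.  Evaluation subsamples the
negatives (seeded) to the requested negative:positive excess — 30:1 by
default, 50:1 for precision-recall plots — because AUPRC depends directly
on class prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

DEFAULT_NEGATIVE_EXCESS = 30


class EvaluationError(ValueError):
    pass


@dataclass
class EvalResult:
    auroc: float
    auprc: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    prc_points: np.ndarray  # (n, 2) columns recall, precision
    n_pos: int
    n_neg: int
    negative_excess: float

    def __post_init__(self) -> None:
        for name, v in (("auroc", self.auroc), ("auprc", self.auprc)):
            if not 0.0 <= v <= 1.0:
                raise EvaluationError(f"{name} {v} outside [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "negative_excess": self.negative_excess,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def curves_to_tsv(self, roc_path: str | Path, prc_path: str | Path) -> None:
        np.savetxt(roc_path, self.roc_points, delimiter="\t", header="fpr\ttpr",
                   comments="")
        np.savetxt(prc_path, self.prc_points, delimiter="\t",
                   header="recall\tprecision", comments="")


def _check_two_classes(y: np.ndarray) -> None:
    if y.sum() == 0 or y.sum() == len(y):
        raise EvaluationError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (pairwise concordance probability)."""
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, step estimator."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise EvaluationError("AUPRC undefined without positives")
    if y.sum() == len(y):
        raise EvaluationError("AUPRC undefined without negatives")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def eval_from_scores(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """EvalResult from raw scores and 0/1 labels, with the negative excess
    taken as observed."""
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    return EvalResult(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        roc_points=np.column_stack([fpr, tpr]),
        prc_points=np.column_stack([recall[::-1], precision[::-1]]),
        n_pos=n_pos,
        n_neg=n_neg,
        negative_excess=n_neg / n_pos,
    )


def evaluate(
    model,
    matrix,
    negative_excess: float = DEFAULT_NEGATIVE_EXCESS,
    seed: int = 0,
    positive_label="positive",
) -> EvalResult:
    """Score a labelled feature matrix at a fixed negative:positive excess.

    Negatives are subsampled (uniform, seeded) to ``negative_excess`` times
    the positive count before metric computation.
    """
    y_all = (np.asarray(matrix.labels) == positive_label).astype(int)
    _check_two_classes(y_all)
    pos_idx = np.flatnonzero(y_all == 1)
    neg_idx = np.flatnonzero(y_all == 0)
    need = int(round(negative_excess * len(pos_idx)))
    if len(neg_idx) < need:
        raise EvaluationError(
            f"insufficient negatives for a {negative_excess}:1 excess: "
            f"need {need}, have {len(neg_idx)}"
        )
    rng = np.random.default_rng(seed)
    keep_neg = np.sort(rng.choice(neg_idx, size=need, replace=False))
    idx = np.sort(np.concatenate([pos_idx, keep_neg]))
    y = y_all[idx]
    scores = model.predict_proba(matrix.values[idx])
    fpr, tpr, _ = roc_curve(y, scores)
    precision, recall, _ = precision_recall_curve(y, scores)
    return EvalResult(
        auroc=float(roc_auc_score(y, scores)),
        auprc=float(average_precision_score(y, scores)),
        roc_points=np.column_stack([fpr, tpr]),
        prc_points=np.column_stack([recall[::-1], precision[::-1]]),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        negative_excess=float(negative_excess),
    )
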