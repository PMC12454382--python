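"""Shallow sigmoid network grading of LOCS III severity, dataset splitting
and the evaluation stack.

Each cataract type (NO, NC, C, P) gets its own two-layer network: a sigmoid
hidden layer and a single sigmoid output unit whose activation, rescaled to
the type's grade range and rounded, *is* the predicted grade.  Grades are
ordinal (NO/NC 0-6, C/P 0-5, grade 0 = normal), which is why a single
regression-style output is used rather than a softmax over classes.
Training is plain full-batch gradient descent on the mean squared error
against targets scaled to [0, 1]; everything is deterministic given the seed.

Evaluation reports the confusion matrix, per-grade precision/recall/F1,
overall accuracy, and one-vs-rest ROC/AUC built from the raw network output:
the score of a sample for grade k is the negated distance of the raw output
to grade k's scaled target.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .imgcore import DataError

logger = logging.getLogger("locsgrade")

GRADE_RANGES: Dict[str, Tuple[int, int]] = {
    "NO": (0, 6),
    "NC": (0, 6),
    "C": (0, 5),
    "P": (0, 5),
}


@dataclass(frozen=True)
class GradeLabel:
    """A LOCS III grade: type NO/NC/C/P with grade 0 (normal) .. max."""

    cataract_type: str
    grade: int

    def __post_init__(self):
        if self.cataract_type not in GRADE_RANGES:
            raise ValueError(f"unknown cataract type {self.cataract_type!r}")
        lo, hi = GRADE_RANGES[self.cataract_type]
        if not lo <= self.grade <= hi:
            raise ValueError(
                f"{self.cataract_type} grade must be in [{lo}, {hi}], "
                f"got {self.grade}")


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(items: Sequence, ratio: float = 0.7, seed: int = 0,
                  stratify_key=None) -> Tuple[list, list]:
    """Disjoint, exhaustive 7:3-style split; |train| = round(ratio * n).

    With ``stratify_key`` (a function item -> class), per-class train counts
    are apportioned by largest remainder so class proportions are preserved
    within one item.  A singleton class cannot be split and goes to the
    training set with a warning.  Deterministic given ``seed``.
    """
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    if stratify_key is None:
        order = rng.permutation(n)
        train = [items[i] for i in order[:n_train]]
        test = [items[i] for i in order[n_train:]]
        return train, test

    groups: Dict = {}
    for i, it in enumerate(items):
        groups.setdefault(stratify_key(it), []).append(i)
    keys = sorted(groups, key=repr)
    quotas = {}
    floors = 0
    for k in keys:
        exact = ratio * len(groups[k])
        quotas[k] = [int(np.floor(exact)), exact - np.floor(exact)]
        floors += quotas[k][0]
    # distribute the remaining train slots by largest fractional part
    for k in sorted(keys, key=lambda k: (-quotas[k][1], repr(k)))[:n_train - floors]:
        quotas[k][0] += 1
    train_idx, test_idx = [], []
    for k in keys:
        idx = groups[k]
        if len(idx) == 1:
            warnings.warn(f"stratified split: singleton class {k!r} assigned "
                          f"to the training set")
            train_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        take = quotas[k][0]
        train_idx.extend(idx[j] for j in perm[:take])
        test_idx.extend(idx[j] for j in perm[take:])
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


# ---------------------------------------------------------------------------
# the shallow network
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class AnnConfig:
    hidden_dim: int = 8
    epochs: int = 20000
    learning_rate: float = 0.5
    seed: int = 0


@dataclass
class AnnModel:
    """Two-layer sigmoid network with a single grade output.

    Inputs are standardized with the stored training mean/scale; the output
    activation in (0, 1) is mapped to ``min_grade + raw * (max_grade -
    min_grade)`` and rounded to the nearest integer grade.
    """

    cataract_type: str
    input_dim: int
    hidden_dim: int
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    min_grade: int
    max_grade: int
    seed: int
    epochs: int
    learning_rate: float
    final_loss: float

    def raw_output(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"feature length {x.shape[1]} != input_dim "
                             f"{self.input_dim}")
        x = (x - self.feat_mean) / self.feat_scale
        h = _sigmoid(x @ self.W1.T + self.b1)
        return _sigmoid(h @ self.W2.T + self.b2)[:, 0]

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnnModel":
        d = json.loads(text)
        for k in ("W1", "b1", "W2", "b2", "feat_mean", "feat_scale"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def train_ann(features, labels: Sequence[GradeLabel],
              cfg: AnnConfig = AnnConfig()) -> AnnModel:
    """Train one grading network by full-batch backpropagation on MSE.

    All labels must share one cataract type; targets are the grades scaled to
    ``(grade - min) / (max - min)``.  Deterministic given ``cfg.seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(labels) or len(labels) == 0:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        raise DataError(f"non-finite feature value in row {int(bad[0])}")
    types = {lab.cataract_type for lab in labels}
    if len(types) != 1:
        raise ValueError(f"labels mix cataract types: {sorted(types)}")
    ctype = types.pop()
    lo, hi = GRADE_RANGES[ctype]
    y = (np.array([lab.grade for lab in labels], dtype=float) - lo) / (hi - lo)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    rng = np.random.default_rng(cfg.seed)
    d, m = X.shape[1], cfg.hidden_dim
    W1 = rng.uniform(-1, 1, (m, d)) * np.sqrt(6.0 / (d + m))
    b1 = np.zeros(m)
    W2 = rng.uniform(-1, 1, (1, m)) * np.sqrt(6.0 / (m + 1))
    b2 = np.zeros(1)

    n = X.shape[0]
    loss = np.inf
    for _ in range(cfg.epochs):
        h = _sigmoid(Xs @ W1.T + b1)
        o = _sigmoid(h @ W2.T + b2)[:, 0]
        err = o - y
        loss = float((err ** 2).mean())
        # backprop through the two sigmoid layers
        do = (2.0 / n) * err * o * (1 - o)          # (n,)
        gW2 = do @ h                                 # (m,)
        gb2 = do.sum()
        dh = np.outer(do, W2[0]) * h * (1 - h)       # (n, m)
        gW1 = dh.T @ Xs
        gb1 = dh.sum(axis=0)
        W2 -= cfg.learning_rate * gW2[None, :]
        b2 -= cfg.learning_rate * gb2
        W1 -= cfg.learning_rate * gW1
        b1 -= cfg.learning_rate * gb1

    return AnnModel(ctype, d, m, W1, b1, W2, b2, mean, scale, lo, hi,
                    cfg.seed, cfg.epochs, cfg.learning_rate, loss)


def predict_grade(model: AnnModel, features) -> Tuple[GradeLabel, float]:
    """Predict a grade (and the raw score) for one feature vector.

    The raw sigmoid output is rescaled to the grade range, rounded to the
    nearest integer (.5 rounds up) and clipped into the valid range.
    """
    raw = float(model.raw_output(np.atleast_2d(features))[0])
    g = model.min_grade + raw * (model.max_grade - model.min_grade)
    grade = int(np.clip(np.floor(g + 0.5), model.min_grade, model.max_grade))
    return GradeLabel(model.cataract_type, grade), raw


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix, per-grade metrics and one-vs-rest ROC/AUC."""

    cataract_type: str
    grades: List[int]                      # row/col order of the matrix
    confusion: np.ndarray                  # rows = true grade, cols = predicted
    precision: Dict[int, float]
    recall: Dict[int, float]
    f1: Dict[int, float]
    per_class_accuracy: Dict[int, float]   # one-vs-rest (TP+TN)/n
    accuracy: float
    auc: Dict[int, float]                  # one-vs-rest, classes with both signs
    macro_auc: float
    roc_points: Dict[int, Tuple[list, list]]  # grade -> (fpr, tpr)
    n: int

    def to_json(self) -> str:
        d = {
            "cataract_type": self.cataract_type,
            "grades": self.grades,
            "confusion": self.confusion.tolist(),
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "per_class_accuracy": {str(k): v
                                   for k, v in self.per_class_accuracy.items()},
            "accuracy": self.accuracy,
            "auc": {str(k): v for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
            "roc_points": {str(k): [list(f), list(t)]
                           for k, (f, t) in self.roc_points.items()},
            "n": self.n,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    def text_table(self) -> str:
        """Human-readable per-grade table (Recall/Precision/F1/Accuracy)."""
        lines = [f"type {self.cataract_type}  n={self.n}  "
                 f"accuracy={self.accuracy:.4f}  macro AUC={self.macro_auc:.4f}",
                 f"{'grade':>6} {'recall':>8} {'precision':>10} {'F1':>8} "
                 f"{'accuracy*':>10}"]
        for g in self.grades:
            lines.append(f"{g:>6} {self.recall[g]:>8.4f} "
                         f"{self.precision[g]:>10.4f} {self.f1[g]:>8.4f} "
                         f"{self.per_class_accuracy[g]:>10.4f}")
        lines.append("(*) per-grade accuracy is one-vs-rest (TP+TN)/n")
        return "\n".join(lines)


def evaluate(true_labels: Sequence[GradeLabel],
             predicted_labels: Sequence[GradeLabel],
             raw_scores: Optional[Sequence[float]] = None) -> EvalReport:
    """Full evaluation of one grader on one test set.

    One-vs-rest ROC/AUC uses, for grade k, the score ``-|raw - t_k|`` where
    ``t_k`` is grade k's scaled target; AUC is trapezoidal.  Classes absent
    from the truth, or without negatives, carry no AUC; the macro AUC is the
    unweighted mean over classes that have one.
    """
    if len(true_labels) != len(predicted_labels) or len(true_labels) == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    types = {lab.cataract_type for lab in true_labels} | \
            {lab.cataract_type for lab in predicted_labels}
    if len(types) != 1:
        raise ValueError(f"evaluation mixes cataract types: {sorted(types)}")
    ctype = types.pop()
    lo, hi = GRADE_RANGES[ctype]
    grades = list(range(lo, hi + 1))
    y_true = np.array([lab.grade for lab in true_labels])
    y_pred = np.array([lab.grade for lab in predicted_labels])
    n = len(y_true)

    k = len(grades)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t - lo, p - lo] += 1

    precision, recall, f1, per_acc = {}, {}, {}, {}
    for i, g in enumerate(grades):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        tn = n - tp - fp - fn
        if tp + fp == 0:
            logger.debug("precision undefined for grade %s (no predictions); "
                         "reported as 0", g)
        precision[g] = float(tp / (tp + fp)) if tp + fp else 0.0
        recall[g] = float(tp / (tp + fn)) if tp + fn else 0.0
        pr, rc = precision[g], recall[g]
        f1[g] = float(2 * pr * rc / (pr + rc)) if pr + rc else 0.0
        per_acc[g] = float((tp + tn) / n)
    accuracy = float(np.trace(confusion) / n)

    auc: Dict[int, float] = {}
    roc_points: Dict[int, Tuple[list, list]] = {}
    if raw_scores is not None:
        raw = np.asarray(raw_scores, dtype=float)
        if raw.shape[0] != n:
            raise ValueError("raw_scores length mismatch")
        for g in grades:
            pos = y_true == g
            if pos.all() or not pos.any():
                continue
            t_g = (g - lo) / (hi - lo)
            score = -np.abs(raw - t_g)
            auc[g] = float(roc_auc_score(pos, score))
            fpr, tpr, _ = roc_curve(pos, score)
            roc_points[g] = (fpr.tolist(), tpr.tolist())
    macro = float(np.mean(list(auc.values()))) if auc else float("nan")

    return EvalReport(ctype, grades, confusion, precision, recall, f1,
                      per_acc, accuracy, auc, macro, roc_points, n)
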