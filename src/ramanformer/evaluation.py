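"""Cross-validated evaluation: stratified folds, confusion matrices, ROC/AUC.

The protocol mirrors a fivefold design: the data of every class are dealt
into five equal portions; each portion serves once as the test set while the
remaining four are randomly re-split 80/20 into training and validation
sets.  The model of the best-validation epoch is evaluated on the held-out
fold, and the fold with the best test accuracy is additionally flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spectra_io import SpectrumSet
from . import transformer_model as tm
from . import baseline_models as bm

__all__ = [
    "FoldAssignment",
    "FoldResult",
    "CVResult",
    "stratified_kfold",
    "train_val_split",
    "confusion_matrix",
    "per_class_accuracy",
    "roc_auc_ovr",
    "run_cross_validation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold index (0..k−1)."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass
class FoldResult:
    fold: int
    test_accuracy: float
    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    roc: list[dict]
    auc: np.ndarray
    train_log: list[dict]


@dataclass
class CVResult:
    folds: list[FoldResult]
    mean_accuracy: float
    best_fold: int
    best_fold_accuracy: float
    mean_auc_per_class: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "best_fold": self.best_fold,
            "best_fold_accuracy": self.best_fold_accuracy,
            "mean_auc_per_class": self.mean_auc_per_class.tolist(),
            "folds": [
                {
                    "fold": f.fold,
                    "test_accuracy": f.test_accuracy,
                    "confusion": f.confusion.tolist(),
                    "per_class_accuracy": f.per_class_accuracy.tolist(),
                    "auc": f.auc.tolist(),
                    "roc": f.roc,
                    "train_log": f.train_log,
                }
                for f in self.folds
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Deal each class's shuffled indices round-robin into k folds."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    fold_index = np.full(labels.size, -1, dtype=int)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < k:
            raise ValueError(f"class {c} too small for {k} folds")
        shuffled = rng.permutation(members)
        for pos, idx in enumerate(shuffled):
            fold_index[idx] = pos % k
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


def train_val_split(indices: np.ndarray, labels: np.ndarray, frac: float,
                    seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of `indices`: round(frac·n) per class to train."""
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    indices = np.asarray(indices, dtype=int)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    train_parts, val_parts = [], []
    for c in np.unique(labels[indices]):
        members = indices[labels[indices] == c]
        n_train = int(np.floor(frac * members.size + 0.5))  # round half up
        if n_train == 0 or n_train == members.size:
            raise ValueError(f"class {c} would vanish from one side of the split")
        shuffled = rng.permutation(members)
        train_parts.append(shuffled[:n_train])
        val_parts.append(shuffled[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts))


def confusion_matrix(true: np.ndarray, predicted: np.ndarray, n_classes: int) -> np.ndarray:
    """C×C count matrix; rows are true classes, columns predictions."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    if true.size and (min(true.min(), predicted.min()) < 0
                      or max(true.max(), predicted.max()) >= n_classes):
        raise ValueError("label out of range")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (true, predicted), 1)
    return mat


def per_class_accuracy(confusion: np.ndarray) -> np.ndarray:
    """Diagonal / row sum; NaN where a class has no support."""
    support = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(support > 0, np.diag(confusion) / support, np.nan)


def _roc_curve(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC by threshold sweep; AUC by the rank/pair formulation.

    Tied score pairs count one half, so the AUC equals the trapezoidal
    integral of the swept curve.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order].astype(float)
    n_pos = pos.sum()
    n_neg = pos.size - n_pos
    tp = np.cumsum(pos)
    fp = np.cumsum(1.0 - pos)
    # collapse runs of equal scores: take the last index of each run
    last = np.flatnonzero(np.append(np.diff(s) != 0, True))
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc_ovr(probabilities: np.ndarray, labels: np.ndarray
                ) -> tuple[list[Optional[dict]], np.ndarray]:
    """Per-class one-vs-rest ROC points and AUC from a probability matrix.

    Returns ``(curves, auc)`` where ``curves[c]`` is ``{"fpr": [...],
    "tpr": [...]}`` (or ``None`` when class c is absent or universal) and
    ``auc[c]`` is the area (NaN when undefined).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, c = probabilities.shape
    curves: list[Optional[dict]] = []
    auc = np.full(c, np.nan)
    for cls in range(c):
        positive = labels == cls
        if positive.sum() == 0 or positive.sum() == n:
            curves.append(None)
            continue
        fpr, tpr, a = _roc_curve(probabilities[:, cls], positive)
        curves.append({"fpr": fpr.tolist(), "tpr": tpr.tolist()})
        auc[cls] = a
    return curves, auc


def _make_model(arch: str, model_cfg, axis: np.ndarray, seed: int,
                class_names: Optional[Sequence[str]]):
    if arch == "transformer":
        return tm.TransformerClassifier(model_cfg, axis, seed=seed,
                                        class_names=class_names)
    return bm.build_classifier(model_cfg, axis, seed=seed, class_names=class_names)


def run_cross_validation(sset: SpectrumSet, arch: str, model_cfg,
                         tcfg: tm.TrainConfig, k: int = 5, seed: int = 0,
                         train_frac: float = 0.8) -> CVResult:
    """Full k-fold protocol over a labeled, preprocessed spectrum set.

    For each fold: the fold is the test set; the pooled remainder is split
    80/20 (stratified) into train/validation; the model is trained fresh and
    the best-validation-epoch parameters are scored on the test fold.
    """
    if sset.labels is None:
        raise ValueError("labeled set required")
    n_classes = sset.n_classes
    assignment = stratified_kfold(sset.labels, k, seed)
    folds: list[FoldResult] = []
    for f in range(k):
        test_idx = assignment.test_indices(f)
        rest = assignment.train_indices(f)
        train_idx, val_idx = train_val_split(rest, sset.labels, train_frac,
                                             seed + 101 * (f + 1))
        # leakage guard: the test fold must be disjoint from both splits
        assert not (set(test_idx) & set(train_idx)) and not (set(test_idx) & set(val_idx))
        model = _make_model(arch, model_cfg, sset.axis, seed + f,
                            sset.class_names)
        _, log = tm.train_model(sset.subset(train_idx), sset.subset(val_idx),
                                model, tcfg)
        pred, probs = tm.predict(model, sset.subset(test_idx))
        true = sset.labels[test_idx]
        conf = confusion_matrix(true, pred, n_classes)
        curves, auc = roc_auc_ovr(probs, true)
        acc = float(np.trace(conf) / conf.sum())
        folds.append(FoldResult(fold=f, test_accuracy=acc, confusion=conf,
                                per_class_accuracy=per_class_accuracy(conf),
                                roc=[c for c in curves], auc=auc, train_log=log))
        logger.info("fold %d: test accuracy %.4f", f, acc)
    accs = np.array([f.test_accuracy for f in folds])
    best = int(np.argmax(accs))  # argmax ties break to the lowest index
    mean_auc = np.nanmean(np.vstack([f.auc for f in folds]), axis=0)
    return CVResult(folds=folds, mean_accuracy=float(accs.mean()),
                    best_fold=best, best_fold_accuracy=float(accs[best]),
                    mean_auc_per_class=mean_auc, seed=seed)
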