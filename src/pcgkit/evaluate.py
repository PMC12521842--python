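"""Classification metrics and leakage-free cross-validation.

Provides the per-class precision/recall/F1 rates, Cohen's kappa, the
polygon area metric (PAM: area of the radar hexagon spanned by
precision, recall, F1, accuracy, one-vs-rest AUC and the Jaccard index,
normalized by the regular unit hexagon), stratified k-fold splitting,
and a cross-validation driver that refits the entire pipeline --
including oversampling and feature selection -- inside each training
fold so that no synthetic or selection information leaks into
validation data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    classes: list
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    pam: float | None = None
    folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"classes": [str(c) for c in self.classes],
             "confusion": self.confusion.tolist(),
             "precision": self.precision.tolist(),
             "recall": self.recall.tolist(),
             "f1": self.f1.tolist(),
             "accuracy": self.accuracy,
             "macro_precision": self.macro_precision,
             "macro_recall": self.macro_recall,
             "macro_f1": self.macro_f1,
             "kappa": self.kappa, "pam": self.pam}
        if self.folds:
            d["folds"] = self.folds
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [f"{'class':>10} {'prec':>7} {'recall':>7} {'f1':>7}"]
        for c, p, r, f in zip(self.classes, self.precision, self.recall,
                              self.f1):
            lines.append(f"{str(c):>10} {p:7.3f} {r:7.3f} {f:7.3f}")
        lines.append(f"accuracy {self.accuracy:.3f}  macro-F1 "
                     f"{self.macro_f1:.3f}  kappa {self.kappa:.3f}"
                     + (f"  PAM {self.pam:.3f}" if self.pam is not None else ""))
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    classes = np.asarray(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def confusion_and_rates(y_true, y_pred, classes) -> EvalReport:
    """Confusion matrix plus per-class precision/recall/F1, accuracy and
    kappa.  Zero-division cases (a class never predicted or never
    present) yield 0 with a warning."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty input")
    cm = confusion_matrix(y_true, y_pred, classes)
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    if np.any(pred_tot == 0):
        warnings.warn("some classes were never predicted; precision set to 0",
                      stacklevel=2)
    acc = float(tp.sum() / cm.sum())
    return EvalReport(classes=list(classes), confusion=cm, precision=prec,
                      recall=rec, f1=f1, accuracy=acc,
                      macro_precision=float(prec.mean()),
                      macro_recall=float(rec.mean()),
                      macro_f1=float(f1.mean()), kappa=kappa(cm))


def kappa(confusion: np.ndarray) -> float:
    """Cohen's chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / total**2)
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


#: area of the regular unit hexagon (radius 1, 60 degree spacing)
_UNIT_HEXAGON_AREA = 3.0 * np.sqrt(3.0) / 2.0


def polygon_area_metric(precision: float, recall: float, f1: float,
                        accuracy: float, auc: float, jaccard: float) -> float:
    """Area of the metric hexagon, normalized to [0, 1].

    The six metrics are radii at 60-degree spacing; the polygon area is
    computed by the shoelace formula and divided by the area of the
    unit hexagon, so six perfect metrics give exactly 1 and uniform
    radii r give r^2.
    """
    r = np.array([precision, recall, f1, accuracy, auc, jaccard], dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("all six metrics must lie in [0, 1]")
    ang = np.arange(6) * np.pi / 3.0
    x, y = r * np.cos(ang), r * np.sin(ang)
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area / _UNIT_HEXAGON_AREA)


def roc_auc_ovr(y_true, proba: np.ndarray, classes) -> float:
    """Macro one-vs-rest AUC from predicted probabilities, via the
    rank-sum (Mann-Whitney) identity.  Classes absent from ``y_true``
    are skipped."""
    y_true = np.asarray(y_true)
    aucs = []
    for i, c in enumerate(classes):
        pos = y_true == c
        n_pos, n_neg = pos.sum(), (~pos).sum()
        if n_pos == 0 or n_neg == 0:
            continue
        # average ranks handle score ties
        order = np.argsort(proba[:, i], kind="stable")
        ranks = np.empty(order.size, dtype=float)
        s = proba[order, i]
        r = np.arange(1, order.size + 1, dtype=float)
        _, inv, cnt = np.unique(s, return_inverse=True, return_counts=True)
        csum = np.concatenate([[0], np.cumsum(cnt)])
        avg = (csum[:-1] + (cnt + 1) / 2.0)
        ranks[order] = avg[inv]
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        aucs.append(auc)
    return float(np.mean(aucs)) if aucs else 0.0


def jaccard_macro(y_true, y_pred, classes) -> float:
    """Macro intersection-over-union: mean of TP / (TP + FP + FN)."""
    cm = confusion_matrix(y_true, y_pred, classes)
    tp = np.diag(cm).astype(float)
    denom = cm.sum(axis=0) + cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        ji = np.where(denom > 0, tp / denom, 0.0)
    return float(ji.mean())


def kfold_split(n: int, k: int, seed: int = 0,
                stratify: np.ndarray | None = None) -> list[np.ndarray]:
    """Seeded (optionally stratified) k-fold index partition.

    Folds are disjoint, exhaustive, and differ in size by at most one;
    with stratification every class is spread across folds, which
    requires each class to appear at least k times.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    if stratify is None:
        idx = rng.permutation(n)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    else:
        stratify = np.asarray(stratify)
        offset = 0
        for c in np.unique(stratify):
            idx = np.where(stratify == c)[0]
            if idx.size < k:
                raise ValueError(f"class {c!r} has {idx.size} < k={k} samples")
            idx = idx[rng.permutation(idx.size)]
            for i, j in enumerate(idx):
                folds[(i + offset) % k].append(j)
            offset += idx.size
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(fit_predict, X, y, k: int = 5, seed: int = 0,
                   classes=None) -> EvalReport:
    """k-fold CV of an arbitrary ``fit_predict(tr_idx, te_idx)`` callable.

    ``fit_predict`` receives the training and validation row indices and
    must return ``(proba, labels)`` for the validation rows, doing all
    fitting (oversampling, selection, training) strictly on the training
    rows.  Per-fold metrics and the pooled confusion are reported.
    """
    y = np.asarray(y)
    classes = np.unique(y) if classes is None else np.asarray(classes)
    folds = kfold_split(y.size, k, seed=seed, stratify=y)
    all_true, all_pred = [], []
    all_proba = []
    fold_metrics = []
    for fi, te in enumerate(folds):
        tr = np.setdiff1d(np.arange(y.size), te)
        proba, labels = fit_predict(tr, te)
        rep = confusion_and_rates(y[te], labels, classes)
        fold_metrics.append({"fold": fi, "accuracy": rep.accuracy,
                             "macro_f1": rep.macro_f1, "kappa": rep.kappa})
        logger.info("fold %d: accuracy %.3f macro-F1 %.3f", fi, rep.accuracy,
                    rep.macro_f1)
        all_true.append(y[te])
        all_pred.append(labels)
        all_proba.append(proba)
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    proba = np.vstack(all_proba)
    report = confusion_and_rates(y_true, y_pred, classes)
    auc = roc_auc_ovr(y_true, proba, classes)
    report.pam = polygon_area_metric(
        min(report.macro_precision, 1.0), min(report.macro_recall, 1.0),
        min(report.macro_f1, 1.0), report.accuracy, auc,
        jaccard_macro(y_true, y_pred, classes))
    report.folds = fold_metrics
    return report
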