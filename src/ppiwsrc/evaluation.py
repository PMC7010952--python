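"""Cross-validation harness and binary-classification metrics.

Metrics follow the usual confusion-matrix definitions: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, and Matthews correlation coefficient
Mcc = (TP.TN - FP.FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any metric whose
denominator vanishes is defined as 0.  AUC is the area under the ROC curve,
equivalently the Mann-Whitney probability that a random positive outscores a
random negative (ties counted 1/2).

``cross_validate`` runs the full encode -> PCA -> pair-vector -> WSRC
pipeline under stratified k-fold cross-validation.  By default the PCA basis
and the representation dictionary are built from the training fold only, so
no information from held-out pairs leaks into the model; ``paper_mode`` fits
the PCA on every protein instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import fit_pca, pair_vector, project, raw_feature
from .wsrc import WSRClassifier

__all__ = [
    "ConfusionCounts",
    "FoldMetrics",
    "MetricsReport",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, Mcc) from confusion counts; 0 on a vanishing denominator."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("no evaluated pairs")
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0
    return sn, sp, acc, mcc


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve of continuous scores against binary labels."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class FoldMetrics:
    fold: int
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float


@dataclass
class MetricsReport:
    """Mean metrics over all folds (and repeats) plus the per-fold breakdown."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    per_fold: list = field(default_factory=list)
    n_folds: int = 5
    repeats: int = 1
    seed: int = 0
    predictions: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("sn", "sp", "acc", "mcc", "auc",
                                           "n_folds", "repeats", "seed")}
        d["per_fold"] = [asdict(f) for f in self.per_fold]
        return d


def _fold_metrics(fold: int, y_true, y_pred, scores) -> FoldMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
    sn, sp, acc, mcc = compute_metrics(counts)
    auc = roc_auc(scores, y_true) if np.unique(y_true).size == 2 else 0.0
    return FoldMetrics(fold=fold, counts=counts, sn=sn, sp=sp, acc=acc,
                       mcc=mcc, auc=auc)


def cross_validate(
    records,
    pairs,
    *,
    L: int = 4,
    k_pca: int = 30,
    epsilon: float = 0.005,
    sigma: float = 1.5,
    weight_mode: str = "literal",
    normalize_query: bool = True,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    stratified: bool = True,
    paper_mode: bool = False,
    scale: bool = False,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the whole pipeline.

    Parameters
    ----------
    records : sequence of objects with ``id`` and ``sequence`` attributes.
    pairs : sequence of objects with ``id_a``, ``id_b`` and ``label``.
    repeats : number of independent CV repetitions averaged into the report
        (10 reproduces a ten-times-five-fold protocol).
    paper_mode : fit the PCA basis on every protein instead of only the
        proteins referenced by training-fold pairs.

    Returns a :class:`MetricsReport` whose headline numbers are per-fold
    means; ``predictions`` holds one row per evaluated pair.
    """
    seq_by_id = {r.id: r.sequence for r in records}
    for p in pairs:
        for pid in (p.id_a, p.id_b):
            if pid not in seq_by_id:
                raise KeyError(f"pair references unknown protein id {pid!r}")
    labels = np.array([int(p.label) for p in pairs])
    if np.unique(labels).size < 2:
        raise ValueError("both interaction labels must be present")

    # per-protein raw encodings are label-free and cached once
    feats = {pid: raw_feature(seq, L=L) for pid, seq in seq_by_id.items()}

    per_fold: list[FoldMetrics] = []
    rows = []
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in ss.generate_state(repeats) % (2**31 - 1)]
    fold_idx = 0
    for rep, rep_seed in enumerate(repeat_seeds):
        if stratified:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                       random_state=rep_seed)
            split = splitter.split(np.zeros(len(pairs)), labels)
        else:
            rng = np.random.default_rng(rep_seed)
            order = rng.permutation(len(pairs))
            chunks = np.array_split(order, folds)
            split = (
                (np.setdiff1d(order, c), c) for c in chunks
            )
        for train_idx, test_idx in split:
            train_pairs = [pairs[i] for i in train_idx]
            test_pairs = [pairs[i] for i in test_idx]
            if paper_mode:
                pca_ids = sorted(seq_by_id)
            else:
                pca_ids = sorted({pid for p in train_pairs for pid in (p.id_a, p.id_b)})
            Xp = np.array([feats[pid] for pid in pca_ids])
            k = min(k_pca, Xp.shape[0] - 1, Xp.shape[1])
            model = fit_pca(Xp, k=k, scale=scale)
            proj = {pid: project(model, f) for pid, f in feats.items()}

            X_train = np.array(
                [pair_vector(proj[p.id_a], proj[p.id_b]) for p in train_pairs]
            )
            y_train = labels[train_idx]
            clf = WSRClassifier(epsilon=epsilon, sigma=sigma,
                                weight_mode=weight_mode,
                                normalize_query=normalize_query)
            clf.fit(X_train, y_train)
            X_test = np.array(
                [pair_vector(proj[p.id_a], proj[p.id_b]) for p in test_pairs]
            )
            sols = clf._solutions(X_test)
            y_pred = np.array([s.label for s in sols])
            scores = np.array([s.score for s in sols])
            y_true = labels[test_idx]
            per_fold.append(_fold_metrics(fold_idx, y_true, y_pred, scores))
            for p, t, pr, sc in zip(test_pairs, y_true, y_pred, scores):
                rows.append((rep, fold_idx, p.id_a, p.id_b, int(t), int(pr),
                             float(sc)))
            fold_idx += 1

    predictions = pd.DataFrame(
        rows, columns=["repeat", "fold", "id_a", "id_b", "label", "predicted",
                       "score"],
    )
    return MetricsReport(
        sn=float(np.mean([f.sn for f in per_fold])),
        sp=float(np.mean([f.sp for f in per_fold])),
        acc=float(np.mean([f.acc for f in per_fold])),
        mcc=float(np.mean([f.mcc for f in per_fold])),
        auc=float(np.mean([f.auc for f in per_fold])),
        per_fold=per_fold,
        n_folds=folds,
        repeats=repeats,
        seed=seed,
        predictions=predictions,
    )
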