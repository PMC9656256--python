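"""Diagnostic classification with pseudo-inverse ("pseudolinear") LDA.

The classifier is linear discriminant analysis with the pooled within-class
covariance inverted by Moore-Penrose pseudo-inverse, so rank-deficient
feature sets (e.g. 13,695 edge weights from 90 subjects) are handled
without regularisation: with class means mu_k, priors pi_k and pooled
covariance S, the discriminant score is

    d_k(x) = x' S+ mu_k - 1/2 mu_k' S+ mu_k + log pi_k

and the posterior is the softmax of the scores.  The pseudo-inverse acts
in the span of the training data (economy SVD of the within-class centred
matrix), which keeps fitting O(n^2 p) rather than O(p^3).

Five feature-vector variants are supported: the full upper-triangle
functional-connectivity vector, the FDR-significant subset of it, and the
three node-measure vectors (clustering, strength, centrality).  Evaluation
is repeated stratified k-fold cross-validation: accuracy is summarised as
mean +/- SD over repeats, sensitivity/specificity/precision come from the
confusion matrix pooled over all out-of-fold predictions (positive class
"depression"), and the ROC/AUC from the pooled out-of-fold posterior
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

FEATURE_VARIANTS = ("full_fc", "significant_fc", "clustering", "strength", "centrality")
POSITIVE_LABEL = "depression"


# ---------------------------------------------------------------------------
# features


def build_features(variant: str, matrices=None, measures=None, mask: np.ndarray | None = None) -> np.ndarray:
    """Subject x feature table for one variant.

    ``full_fc``/``significant_fc`` need connectivity ``matrices`` (the
    latter also a symmetric 0/1 ``mask``); the node variants need
    ``measures`` (a list of NodeMeasureSet).  Edge features follow fixed
    row-major upper-triangle (i < j) order.
    """
    if variant not in FEATURE_VARIANTS:
        raise ValueError(f"unknown feature variant {variant!r}")
    if variant in ("full_fc", "significant_fc"):
        if matrices is None:
            raise ValueError(f"variant {variant!r} requires connectivity matrices")
        from .edge_stats import stack_edges

        Y, rows, cols, _ = stack_edges(matrices)
        if variant == "full_fc":
            return Y
        if mask is None:
            raise ValueError("variant 'significant_fc' requires an edge mask")
        mask = np.asarray(mask)
        keep = mask[rows, cols].astype(bool)
        return Y[:, keep]
    if measures is None:
        raise ValueError(f"variant {variant!r} requires node measure sets")
    return np.stack([np.asarray(getattr(m, variant), dtype=float) for m in measures])


# ---------------------------------------------------------------------------
# pseudolinear LDA


@dataclass
class LdaModel:
    """Fitted pseudo-inverse LDA for two (or more) classes."""

    classes_: np.ndarray
    priors_: np.ndarray
    means_: np.ndarray = field(repr=False)
    _basis: np.ndarray = field(default=None, repr=False)  # p x r, columns span data
    _inv_var: np.ndarray = field(default=None, repr=False)  # r, 1/singular values^2

    def _discriminants(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xb = X @ self._basis  # n x r
        Mb = self.means_ @ self._basis  # K x r
        cross = (Xb * self._inv_var) @ Mb.T
        quad = 0.5 * np.sum(Mb * Mb * self._inv_var, axis=1)
        return cross - quad[None, :] + np.log(self.priors_)[None, :]

    def decision_function(self, X) -> np.ndarray:
        """Binary discriminant: score of the last class minus the first."""
        d = self._discriminants(X)
        return d[:, -1] - d[:, 0]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._discriminants(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        d = self._discriminants(X)
        d = d - d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)


def lda_fit(X, y, priors: str = "empirical") -> LdaModel:
    """Fit pseudo-inverse LDA.  ``priors``: "empirical" or "uniform"."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 members")
    n, _ = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    centered = X - means[np.searchsorted(classes, y)]
    # economy SVD of the within-class centred matrix: pooled covariance
    # S = V diag(s^2/(n-K)) V'; pseudo-inverse acts in span(V).
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not keep.any():
        raise ValueError("within-class covariance is identically zero")
    basis = vt[keep].T
    inv_var = (n - len(classes)) / (s[keep] ** 2)
    if priors == "empirical":
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    return LdaModel(classes_=classes, priors_=pri, means_=means, _basis=basis, _inv_var=inv_var)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ClassificationReport:
    """Repeated-CV performance summary for one feature variant."""

    variant: str
    accuracy_mean: float
    accuracy_sd: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float
    confusion: dict  # pooled over repeats: tp, fp, tn, fn (positive = depression)
    roc: dict = field(repr=False)  # fpr, tpr lists
    k: int = 10
    repeats: int = 1000
    seed: int = 0
    accuracies: np.ndarray = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "feature_vector": self.variant,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
        }


def cross_validate(
    X,
    y,
    k: int = 10,
    repeats: int = 1000,
    seed: int = 0,
    priors: str = "empirical",
    variant: str = "",
    selector=None,
) -> ClassificationReport:
    """Repeated stratified k-fold CV of pseudo-inverse LDA.

    ``selector(X, y, train_idx) -> column indices`` optionally recomputes a
    feature subset inside every training fold (used to rebuild the
    significant-edge mask without selection bias); when absent all columns
    are used.  Per-repeat fold assignment reshuffles from a stream derived
    from ``seed``; the whole report is deterministic given it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("cross_validate expects exactly two classes")
    if POSITIVE_LABEL in classes:
        pos = POSITIVE_LABEL
    else:
        pos = classes[-1]
    min_count = min((y == c).sum() for c in classes)
    if k > min_count:
        raise ValueError(
            f"k={k} folds cannot each contain both classes (smallest class has {min_count})"
        )

    fold_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    accuracies = np.empty(repeats)
    tp = fp = tn = fn = 0
    scores_all, truth_all = [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[r]))
        correct = 0
        for train_idx, test_idx in skf.split(X, y):
            cols = None if selector is None else np.asarray(selector(X, y, train_idx))
            Xtrain = X[train_idx] if cols is None else X[train_idx][:, cols]
            Xtest = X[test_idx] if cols is None else X[test_idx][:, cols]
            model = lda_fit(Xtrain, y[train_idx], priors=priors)
            pred = model.predict(Xtest)
            truth = y[test_idx]
            correct += int((pred == truth).sum())
            is_pos = truth == pos
            pred_pos = pred == pos
            tp += int((pred_pos & is_pos).sum())
            fp += int((pred_pos & ~is_pos).sum())
            tn += int((~pred_pos & ~is_pos).sum())
            fn += int((~pred_pos & is_pos).sum())
            sign = 1.0 if model.classes_[-1] == pos else -1.0
            scores_all.append(sign * model.decision_function(Xtest))
            truth_all.append(is_pos)
        accuracies[r] = correct / len(y)

    scores = np.concatenate(scores_all)
    truths = np.concatenate(truth_all)
    fpr, tpr, _ = roc_curve(truths, scores, drop_intermediate=False)
    area = float(_auc(fpr, tpr))
    total = tp + fp + tn + fn
    assert total == repeats * len(y)
    report = ClassificationReport(
        variant=variant,
        accuracy_mean=float(accuracies.mean()),
        accuracy_sd=float(accuracies.std(ddof=1)) if repeats > 1 else 0.0,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        auc=area,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc={"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        k=k,
        repeats=repeats,
        seed=seed,
        accuracies=accuracies,
    )
    # pooled-confusion identity: pooled accuracy equals (tp + tn) / total
    assert abs((tp + tn) / total - accuracies.mean()) < 1e-12
    return report


def reports_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
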