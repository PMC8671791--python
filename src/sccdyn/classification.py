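"""Temporal-expression features and leave-one-out SVM classification.

Each subject is summarized by 2k numbers: the mean intensity and the temporal
variance of its expression time course for each of the k components, in
ranked component order. Classification is leave-one-out: in every fold the
components are re-learned from the training subjects alone, training
subjects' temporal matrices are the row blocks of the group temporal factor,
the held-out subject's temporal matrix is obtained by projecting its stack
onto the fold's (unit-row-normalized) loadings, features are z-scored with
training-fold statistics, and a linear SVM (fixed regularization C = 1)
predicts the held-out label. Nothing from the held-out subject touches the
fold's component learning or scaling, so chance-level accuracy under a null
generator is a leakage check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .dfc import WindowedConnectome, concatenate_subjects
from .decomposition import learn_group_sccs, unit_row_form
from .model_selection import project_temporal

__all__ = [
    "TemporalFeatures",
    "ClassificationResult",
    "temporal_features",
    "loocv_classify",
    "sweep_k",
]


def temporal_features(t_i: np.ndarray) -> np.ndarray:
    """Per-component mean intensity and temporal variance, concatenated (2k).

    Means are signed; variances use the unbiased (w - 1) denominator. Columns
    are assumed to already be in ranked component order.
    """
    T = np.asarray(t_i, dtype=float)
    if T.ndim != 2:
        raise ValueError("temporal matrix must be 2-D (windows x components)")
    if T.shape[0] < 2:
        raise ValueError("need at least 2 windows for a temporal variance")
    return np.concatenate([T.mean(axis=0), T.var(axis=0, ddof=1)])


@dataclass
class TemporalFeatures:
    """Subjects x 2k feature table (k means then k variances)."""

    values: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[1] != 2 * self.k:
            raise ValueError("feature table must have 2k columns")


@dataclass
class ClassificationResult:
    """Leave-one-out metrics for one component count k."""

    k: int
    fold_predictions: np.ndarray
    labels: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    seed: int = 0
    lambda_: float = 0.0


def _metrics(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


def _zscore_train_test(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize with training statistics; constant columns map to 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    tr = (train - mu) / safe
    te = (test - mu) / safe
    tr[:, sd == 0] = 0.0
    te[:, sd == 0] = 0.0
    return tr, te


def loocv_classify(
    subjects: list[WindowedConnectome],
    labels,
    k: int,
    lambda_: float,
    seed: int = 0,
    svm_c: float = 1.0,
    standardize: bool = True,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> ClassificationResult:
    """Leave-one-out linear-SVM discrimination from temporal features.

    Labels are 0 (control) / 1 (patient); sensitivity is recall on the
    patient class, specificity recall on controls.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(subjects)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if labels.shape != (n,):
        raise ValueError("labels must match the subject list")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    preds = np.empty(n, dtype=int)
    for held in range(n):
        train_idx = [i for i in range(n) if i != held]
        if len(np.unique(labels[train_idx])) < 2:
            raise ValueError(
                f"training fold {held} contains a single class"
            )
        stack = concatenate_subjects([subjects[i] for i in train_idx])
        dec = learn_group_sccs(
            stack, k=k, lambda_=lambda_, seed=seed,
            max_iter=max_iter, tol=tol,
        )
        T_scaled, C_unit = unit_row_form(dec)
        feats_train = np.stack([
            temporal_features(T_scaled[stack.subject_slice(j)])
            for j in range(len(train_idx))
        ])
        t_test = project_temporal(subjects[held], C_unit)
        feat_test = temporal_features(t_test)[None, :]
        if standardize:
            feats_train, feat_test = _zscore_train_test(
                feats_train, feat_test
            )
        clf = SVC(kernel="linear", C=svm_c)
        clf.fit(feats_train, labels[train_idx])
        preds[held] = int(clf.predict(feat_test)[0])

    acc, sens, spec = _metrics(preds, labels)
    return ClassificationResult(
        k=k, fold_predictions=preds, labels=labels,
        accuracy=acc, sensitivity=sens, specificity=spec,
        seed=seed, lambda_=lambda_,
    )


@dataclass
class KSweepResult:
    results: list[ClassificationResult]
    best_k: int = field(init=False)

    def __post_init__(self) -> None:
        accs = [r.accuracy for r in self.results]
        best = int(np.argmax(accs))  # argmax takes the first (smallest k) tie
        self.best_k = self.results[best].k


def sweep_k(
    subjects: list[WindowedConnectome],
    labels,
    k_values: list[int],
    lambda_: float,
    seed: int = 0,
    **kwargs,
) -> KSweepResult:
    """Full LOOCV at every k; ties in accuracy resolve to the smaller k."""
    k_values = sorted(int(k) for k in k_values)
    results = [
        loocv_classify(subjects, labels, k=ki, lambda_=lambda_, seed=seed,
                       **kwargs)
        for ki in k_values
    ]
    return KSweepResult(results=results)
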