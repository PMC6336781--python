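"""Whole-brain linear-SVM classification.

Subjects are points in voxel space; a soft-margin linear SVM is trained on
a precomputed Gram matrix, evaluated with leave-one-pair-out
cross-validation (one patient + one control held out per fold),
significance-tested by label permutation, and summarized by a voxelwise
discrimination (weight) map thresholded at a fraction of its maximum
absolute value.

The quadratic-programming solver behind :func:`train_svm` is
scikit-learn's ``SVC(kernel="precomputed")``; everything around it (fold
construction, metrics, permutation scheme, weight-map algebra) is defined
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .types import CohortFeatures

DEFAULT_C = 1.0
DEFAULT_THRESHOLD_FRACTION = 0.30


@dataclass
class SvmModel:
    """Trained soft-margin dual solution on a precomputed linear kernel.

    ``alpha_signed`` holds alpha_i * y_i for the support vectors, so the
    decision function is f(x) = sum_i alpha_signed_i K(x_i, x) + bias.
    """

    alpha_signed: np.ndarray
    support_idx: np.ndarray
    bias: float
    C: float
    n_train: int

    def decision_from_kernel(self, kernel_rows: np.ndarray) -> np.ndarray:
        """Decision values given kernel rows K(test, train) of shape
        (n_test, n_train)."""
        rows = np.atleast_2d(kernel_rows)
        if rows.shape[1] != self.n_train:
            raise ValueError("kernel rows do not match training size")
        return rows[:, self.support_idx] @ self.alpha_signed + self.bias


@dataclass
class DiscriminationMap:
    """Voxelwise SVM weights mapped back to the grid; positive weights point
    toward the patient class."""

    weights: np.ndarray  # 3D grid
    voxel_index: tuple[np.ndarray, np.ndarray, np.ndarray]
    kind: str


@dataclass
class CVReport:
    """Leave-one-pair-out results: per-subject predictions, confusion
    counts, the performance triplet (percent), AUC, and (optionally) the
    permutation p-value."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray
    fold_of_subject: np.ndarray
    C: float
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    accuracy_pct: float = float("nan")
    sensitivity_pct: float = float("nan")
    specificity_pct: float = float("nan")
    auc: float = float("nan")
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": len(self.subject_ids),
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "accuracy_pct": round(self.accuracy_pct, 2),
            "sensitivity_pct": round(self.sensitivity_pct, 2),
            "specificity_pct": round(self.specificity_pct, 2),
            "auc": round(self.auc, 4) if np.isfinite(self.auc) else None,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "C": self.C,
        }


def linear_kernel(features: CohortFeatures | np.ndarray) -> np.ndarray:
    """Gram matrix of subject rows (plain inner products, no centering)."""
    X = features.matrix if isinstance(features, CohortFeatures) else np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X @ X.T


def train_svm(kernel: np.ndarray, labels: np.ndarray, C: float = DEFAULT_C) -> SvmModel:
    """Fit the soft-margin dual problem on a precomputed kernel."""
    K = np.asarray(kernel, dtype=float)
    y = np.asarray(labels, dtype=int)
    if K.shape[0] != K.shape[1] or K.shape[0] != y.shape[0]:
        raise ValueError("kernel must be square and match the label count")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K, y)
    # sklearn's dual_coef_ is alpha_i * y_i ordered by support_
    return SvmModel(
        alpha_signed=clf.dual_coef_.ravel().copy(),
        support_idx=clf.support_.copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        n_train=y.shape[0],
    )


def default_pairing(labels: np.ndarray) -> list[tuple[int, int]]:
    """Pair the i-th patient with the i-th control in table order."""
    y = np.asarray(labels)
    patients = np.nonzero(y == 1)[0]
    controls = np.nonzero(y == -1)[0]
    if patients.size != controls.size:
        raise ValueError(
            f"unequal group sizes ({patients.size} patients, {controls.size} "
            "controls); supply an explicit pairing"
        )
    return list(zip(patients.tolist(), controls.tolist()))


def loocv_pairs(
    features: CohortFeatures | np.ndarray,
    labels: np.ndarray | None = None,
    C: float = DEFAULT_C,
    pairing: list[tuple[int, int]] | None = None,
    subject_ids: list[str] | None = None,
    kernel: np.ndarray | None = None,
) -> CVReport:
    """Leave-one-pair-out cross-validation.

    Each fold holds out one (patient, control) pair, trains on the rest,
    and records held-out decision values; every subject is predicted
    exactly once. The Gram matrix is computed once and sub-indexed.
    """
    if isinstance(features, CohortFeatures):
        labels = features.labels if labels is None else np.asarray(labels)
        subject_ids = subject_ids or features.subject_ids
    y = np.asarray(labels, dtype=int)
    n = y.shape[0]
    subject_ids = subject_ids or [f"s{i}" for i in range(n)]
    if pairing is None:
        pairing = default_pairing(y)
    covered = sorted(i for pair in pairing for i in pair)
    if covered != list(range(n)):
        raise ValueError("pairing must cover every subject exactly once")
    K = linear_kernel(features) if kernel is None else np.asarray(kernel, dtype=float)

    y_pred = np.zeros(n, dtype=int)
    decisions = np.zeros(n)
    fold_of = np.zeros(n, dtype=int)
    for fold, (i_pat, i_ctrl) in enumerate(pairing):
        test = np.array([i_pat, i_ctrl])
        train = np.setdiff1d(np.arange(n), test)
        model = train_svm(K[np.ix_(train, train)], y[train], C=C)
        dec = model.decision_from_kernel(K[np.ix_(test, train)])
        decisions[test] = dec
        y_pred[test] = np.where(dec >= 0, 1, -1)
        fold_of[test] = fold
    report = CVReport(
        subject_ids=list(subject_ids),
        y_true=y,
        y_pred=y_pred,
        decision_values=decisions,
        fold_of_subject=fold_of,
        C=C,
    )
    return score_report(report)


def score(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    Sensitivity is the correct fraction among patients (+1), specificity
    among controls (-1).
    """
    y_pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if y_pred.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((y == 1) & (y_pred == 1)))
    fn = int(np.sum((y == 1) & (y_pred == -1)))
    tn = int(np.sum((y == -1) & (y_pred == -1)))
    fp = int(np.sum((y == -1) & (y_pred == 1)))
    acc = 100.0 * (tp + tn) / max(tp + fn + tn + fp, 1)
    sens = 100.0 * tp / max(tp + fn, 1)
    spec = 100.0 * tn / max(tn + fp, 1)
    return acc, sens, spec


def score_report(report: CVReport) -> CVReport:
    """Fill the confusion counts, triplet and AUC of a CVReport in place."""
    y, y_pred = report.y_true, report.y_pred
    report.tp = int(np.sum((y == 1) & (y_pred == 1)))
    report.fn = int(np.sum((y == 1) & (y_pred == -1)))
    report.tn = int(np.sum((y == -1) & (y_pred == -1)))
    report.fp = int(np.sum((y == -1) & (y_pred == 1)))
    acc, sens, spec = score(y_pred, y)
    report.accuracy_pct = acc
    report.sensitivity_pct = sens
    report.specificity_pct = spec
    report.auc = roc_auc(report.decision_values, y)
    return report


def roc_auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC over pooled decision values (ties count 1/2)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(decision_values, dtype=float)))


def permutation_test(
    features: CohortFeatures | np.ndarray,
    labels: np.ndarray | None = None,
    C: float = DEFAULT_C,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "accuracy",
) -> tuple[float, np.ndarray]:
    """Label-permutation significance of the LOOCV performance.

    Each permutation reruns the full leave-one-pair-out procedure with
    shuffled labels. ``statistic="accuracy"`` counts permutations whose
    accuracy >= observed; ``"joint"`` counts those with both sensitivity
    and specificity >= observed. Returns the add-one p-value
    (1 + b) / (1 + n_perm) and the permuted statistic values (accuracy, or
    (sens, spec) rows for joint).
    """
    if statistic not in ("accuracy", "joint"):
        raise ValueError("statistic must be 'accuracy' or 'joint'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(features, CohortFeatures):
        labels = features.labels if labels is None else np.asarray(labels)
    y = np.asarray(labels, dtype=int)
    K = linear_kernel(features)
    observed = loocv_pairs(K if not isinstance(features, CohortFeatures) else features,
                           labels=y, C=C, kernel=K)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm_stats = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        rep = loocv_pairs(K, labels=y_perm, C=C, kernel=K)
        if statistic == "accuracy":
            perm_stats.append(rep.accuracy_pct)
            exceed += rep.accuracy_pct >= observed.accuracy_pct
        else:
            perm_stats.append((rep.sensitivity_pct, rep.specificity_pct))
            exceed += (
                rep.sensitivity_pct >= observed.sensitivity_pct
                and rep.specificity_pct >= observed.specificity_pct
            )
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p, np.asarray(perm_stats)


def discrimination_map(
    model: SvmModel, features: CohortFeatures
) -> DiscriminationMap:
    """Map the primal weight vector w = sum_i alpha_i y_i x_i back to the
    grid. Positive weights favor the patient class."""
    if model.n_train != features.n_subjects:
        raise ValueError("model was not trained on this cohort")
    w = model.alpha_signed @ features.matrix[model.support_idx]
    grid = np.zeros(features.grid_shape)
    grid[features.voxel_index] = w
    return DiscriminationMap(weights=grid, voxel_index=features.voxel_index,
                             kind=features.kind)


def threshold_map(
    dmap: DiscriminationMap, fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> np.ndarray:
    """Retain voxels with |w| strictly above fraction * max |w|; returns the
    sign-preserving thresholded weight grid (0 elsewhere)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    w = dmap.weights
    w_max = np.abs(w).max()
    if w_max == 0:
        raise ValueError("all-zero discrimination map")
    retained = np.abs(w) > fraction * w_max
    return np.where(retained, w, 0.0)


def confusion_from_rates(
    sensitivity_pct: float, specificity_pct: float, n_per_group: int
) -> tuple[int, int]:
    """Recover integer per-class correct counts from printed percentages.

    Returns (patients correct, controls correct); raises if no integer
    count reproduces a printed rate at 2-decimal rounding.
    """
    counts = []
    for pct in (sensitivity_pct, specificity_pct):
        candidates = [
            c for c in range(n_per_group + 1)
            if round(100.0 * c / n_per_group, 2) == round(pct, 2)
        ]
        if len(candidates) != 1:
            raise ValueError(
                f"{pct}% is not uniquely realizable as c/{n_per_group} "
                f"(candidates: {candidates})"
            )
        counts.append(candidates[0])
    return counts[0], counts[1]
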