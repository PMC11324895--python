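"""Comprehension-condition classification from match-mismatch accuracies.

Each subject contributes, per condition and linguistic level, a 4-vector of
MM accuracies — (control, linguistic) x (language fine-tune, subject
fine-tune) — and an RBF-kernel SVM solves one-vs-one condition tasks under
nested cross-validation: leave-one-subject-out outer folds (both of a
subject's vectors leave together) and grouped 5-fold inner search over the
margin parameter C and the kernel width. Outer-fold decision scores are
pooled into one ROC; threshold-at-zero predictions give accuracy, F1,
sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FEATURE_ORDER = [("C", "FTL"), ("L", "FTL"), ("C", "FTS"), ("L", "FTS")]
C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
GAMMA_SCALE_GRID = (0.1, 1.0, 10.0)  # multiples of sklearn's 'scale' gamma


@dataclass
class SubjectFeatureVector:
    subject: str
    condition: str
    values: np.ndarray  # 4 MM accuracies, FEATURE_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError("expected exactly 4 accuracy values")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class ClassifierReport:
    task: tuple[str, str]  # (positive condition, negative condition)
    subjects: list[str]
    scores: np.ndarray  # pooled outer-fold decision scores
    labels: np.ndarray  # 1 = first-listed (positive) condition
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    chosen_params: list[dict] = field(default_factory=list)

    def consistency_check(self) -> bool:
        """Point metrics recomputed from the confusion matrix must agree."""
        pred = (self.scores > 0).astype(int)
        tn, fp, fn, tp = confusion_matrix(self.labels, pred, labels=[0, 1]).ravel()
        acc = (tp + tn) / (tp + tn + fp + fn)
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        return bool(
            np.isclose(acc, self.accuracy)
            and np.isclose(sens, self.sensitivity)
            and np.isclose(spec, self.specificity)
            and np.isclose(f1, self.f1)
        )


def assemble_features(
    table: pd.DataFrame, level: str
) -> list[SubjectFeatureVector]:
    """One 4-vector per (subject, condition) from an accuracy table."""
    vectors = []
    for (subject, condition), grp in table[table.level == level].groupby(
        ["subject", "condition"], sort=True
    ):
        values = []
        for fs_name, ft in FEATURE_ORDER:
            rows = grp[(grp.feature_set == fs_name) & (grp.finetune == ft)]
            if len(rows) != 1:
                raise KeyError(
                    f"missing accuracy cell ({subject}, {condition}, {level}, "
                    f"{fs_name}, {ft})"
                )
            values.append(float(rows.mm_accuracy.iloc[0]))
        vectors.append(SubjectFeatureVector(subject, condition, np.array(values)))
    return vectors


def roc_metrics(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float, float, float, float]:
    """(fpr, tpr, auc, accuracy, f1, sensitivity, specificity); predictions
    threshold the decision scores at zero."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need scores from both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    pred = (scores > 0).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    accuracy = (tp + tn) / len(labels)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return fpr, tpr, auc, float(accuracy), float(f1), float(sensitivity), float(specificity)


def _grouped_kfold(subjects: np.ndarray, n_splits: int) -> list[np.ndarray]:
    uniq = np.unique(subjects)
    folds = [uniq[i::n_splits] for i in range(n_splits)]
    return [np.isin(subjects, f) for f in folds]


def _inner_select(x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> dict:
    """Grouped 5-fold accuracy search over (C, kernel width)."""
    n_splits = min(5, len(np.unique(groups)))
    masks = _grouped_kfold(groups, n_splits)
    best = {"acc": -1.0, "C": 1.0, "gamma_mult": 1.0}
    for c in C_GRID:
        for gm in GAMMA_SCALE_GRID:
            correct = total = 0
            for mask in masks:
                if mask.all() or (~mask).all():
                    continue
                scaler = StandardScaler().fit(x[~mask])
                xt, xv = scaler.transform(x[~mask]), scaler.transform(x[mask])
                gamma = gm / (x.shape[1] * xt.var()) if xt.var() > 0 else "scale"
                clf = SVC(kernel="rbf", C=c, gamma=gamma).fit(xt, y[~mask])
                correct += (clf.predict(xv) == y[mask]).sum()
                total += mask.sum()
            acc = correct / total if total else -1.0
            if acc > best["acc"]:
                best = {"acc": acc, "C": c, "gamma_mult": gm}
    return best


def nested_cv_svm(
    vectors: list[SubjectFeatureVector], task: tuple[str, str]
) -> ClassifierReport:
    """Leave-one-subject-out nested cross-validation for one condition pair.

    ``task = (positive, negative)``: the first-listed condition is the
    positive class. Both of a held-out subject's vectors leave together; the
    inner search never sees them.
    """
    pos, neg = task
    rows = [v for v in vectors if v.condition in task]
    subjects = sorted({v.subject for v in rows})
    by_subject: dict[str, dict[str, SubjectFeatureVector]] = {}
    for v in rows:
        by_subject.setdefault(v.subject, {})[v.condition] = v
    for s in subjects:
        if set(by_subject[s]) != set(task):
            raise ValueError(f"subject {s!r} lacks a vector for one condition")

    x = np.array([by_subject[s][c].values for s in subjects for c in task])
    y = np.array([1 if c == pos else 0 for _ in subjects for c in task])
    groups = np.array([s for s in subjects for _ in task])

    scores = np.empty(len(x))
    chosen = []
    for s in subjects:
        test = groups == s
        best = _inner_select(x[~test], y[~test], groups[~test])
        scaler = StandardScaler().fit(x[~test])
        xt = scaler.transform(x[~test])
        gamma = (
            best["gamma_mult"] / (x.shape[1] * xt.var()) if xt.var() > 0 else "scale"
        )
        clf = SVC(kernel="rbf", C=best["C"], gamma=gamma).fit(xt, y[~test])
        scores[test] = clf.decision_function(scaler.transform(x[test]))
        chosen.append({"subject": s, **best})

    fpr, tpr, auc, acc, f1, sens, spec = roc_metrics(scores, y)
    return ClassifierReport(
        task=task, subjects=subjects, scores=scores, labels=y,
        fpr=fpr, tpr=tpr, auc=auc, accuracy=acc, f1=f1,
        sensitivity=sens, specificity=spec, chosen_params=chosen,
    )


def permutation_null_auc(
    vectors: list[SubjectFeatureVector],
    task: tuple[str, str],
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null AUC distribution: per permutation, each subject's two condition
    labels are independently swapped or kept (the paired-design null), and
    the full nested CV is re-run. The identity pattern (no swaps) is always
    excluded; when fewer than ``n_permutations`` distinct non-identity
    patterns exist they are enumerated exhaustively instead of sampled."""
    rng = np.random.default_rng(seed)
    subjects = sorted({v.subject for v in vectors if v.condition in task})
    n = len(subjects)
    if 2**n - 1 <= n_permutations:
        patterns = [
            [(code >> i) & 1 for i in range(n)] for code in range(1, 2**n)
        ]
    else:
        seen = {tuple([0] * n)}
        patterns = []
        while len(patterns) < n_permutations:
            pattern = tuple(rng.integers(0, 2, n))
            if pattern not in seen:
                seen.add(pattern)
                patterns.append(list(pattern))
    aucs = np.empty(len(patterns))
    for i, pattern in enumerate(patterns):
        flips = dict(zip(subjects, pattern))
        permuted = []
        for v in vectors:
            if v.condition not in task:
                continue
            cond = v.condition
            if flips[v.subject]:
                cond = task[1] if cond == task[0] else task[0]
            permuted.append(SubjectFeatureVector(v.subject, cond, v.values.copy()))
        aucs[i] = nested_cv_svm(permuted, task).auc
    return aucs


def plot_roc(report: ClassifierReport, path: str) -> None:
    """Save the pooled-scores ROC curve (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.fpr, report.tpr, label=f"AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"{report.task[0]} vs {report.task[1]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
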