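"""Phenotype classification and group statistics on cell feature tables.

The classifier follows a deliberately simple, auditable recipe: z-score each
feature (sample sd, n-1), train a linear soft-margin SVM (C=1, one-vs-one
for more than two classes) and estimate accuracy with stratified k-fold
cross-validation, pooling out-of-fold predictions into a confusion matrix.
Class subsets and mergers (e.g. collapsing three classes into one against a
fourth) are expressed with a merge specification applied to the label
vector before cross-validation.

Univariate feature relevance between two classes is the one-way ANOVA F
ratio (between-class over within-class mean square); heterogeneity of a
metric within a group is its coefficient of variation (100 * sd / |mean|).
Group differences are assessed with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class ClassificationReport:
    """Cross-validation result for one classification task."""

    task: str
    classes: list[str]
    fold_accuracies: list[float]  # percent, one entry per fold
    confusion_matrix: np.ndarray  # true class x predicted class, pooled
    seed: int

    @property
    def average_accuracy(self) -> float:
        """Mean of per-fold accuracies, percent."""
        return float(np.mean(self.fold_accuracies))


@dataclass
class FeatureRanking:
    """Features ordered by descending univariate F score."""

    features: list[str]
    scores: np.ndarray

    @property
    def ranked(self) -> list[tuple[str, float]]:
        order = np.argsort(-self.scores, kind="stable")  # ties keep column order
        return [(self.features[i], float(self.scores[i])) for i in order]


def zscore(matrix: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring with sample (n-1) standard deviation."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least two rows")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"constant column(s) at index {bad}: z-score undefined")
    return (x - x.mean(axis=0)) / sd


def merge_classes(
    labels: np.ndarray, merge_spec: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel according to ``merge_spec``; rows of unmapped classes drop.

    Returns (keep_index, new_labels). E.g. {"A": "ABC", "B": "ABC",
    "C": "ABC", "D": "D"} builds the binary ABC-vs-D task.
    """
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    unknown = set(merge_spec) - present
    if unknown:
        raise ValueError(f"merge spec names absent class(es): {sorted(unknown)}")
    keep = np.array([lab in merge_spec for lab in labels])
    if not keep.any():
        raise ValueError("merge spec drops every row")
    new_labels = np.array([merge_spec[lab] for lab in labels[keep]])
    return np.nonzero(keep)[0], new_labels


def cross_validated_svm(
    matrix: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    task: str = "",
    stratify: bool = True,
    scale_in_folds: bool = False,
) -> ClassificationReport:
    """k-fold cross-validated linear SVM accuracy with pooled confusion matrix.

    ``matrix`` should already be z-scored unless ``scale_in_folds`` is set,
    in which case z-scoring is fit on each training fold only (leakage-safe
    mode, used for permutation sanity checks).
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        small = classes[counts < k].tolist()
        raise ValueError(
            f"class(es) {small} have fewer than k={k} members; use a smaller k"
        )
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratify
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    class_index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc: list[float] = []
    for train, test in splitter.split(x, labels):
        xtr, xte = x[train], x[test]
        if scale_in_folds:
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(xtr, labels[train])
        pred = clf.predict(xte)
        fold_acc.append(100.0 * float(np.mean(pred == labels[test])))
        for t, p in zip(labels[test], pred):
            conf[class_index[t], class_index[p]] += 1
    return ClassificationReport(
        task=task or "+".join(map(str, classes)),
        classes=[str(c) for c in classes],
        fold_accuracies=fold_acc,
        confusion_matrix=conf,
        seed=seed,
    )


def univariate_f_scores(
    matrix: np.ndarray, labels: np.ndarray, feature_names: list[str] | None = None
) -> FeatureRanking:
    """One-way ANOVA F score per feature between exactly two classes."""
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if np.any(counts < 2):
        raise ValueError("each class needs at least two members")
    scores, _ = f_classif(x, labels)
    names = feature_names or [f"f{i}" for i in range(x.shape[1])]
    return FeatureRanking(features=list(names), scores=np.asarray(scores))


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV% = 100 * sample sd / |mean|; undefined for zero mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def group_compare(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05):
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Returns (anova_f, anova_p, tukey_frame) where the frame has one row per
    pair with the mean difference, adjusted p-value and 95% CI bounds.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 values each")
    samples = [values[groups == g] for g in uniq]
    f, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return float(f), float(p), frame


# ---------------------------------------------------------------------------
# convenience wrappers over feature tables

def feature_matrix_from_table(
    table: pd.DataFrame, feature_columns: list[str], label_column: str = "class"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (matrix, labels) from a feature table, dropping incomplete rows."""
    sub = table.dropna(subset=feature_columns)
    return sub[feature_columns].to_numpy(float), sub[label_column].to_numpy()


TASKS: dict[str, dict[str, str] | None] = {
    "ABCD": None,
    "ACD": {"A": "A", "C": "C", "D": "D"},
    "ABCvD": {"A": "ABC", "B": "ABC", "C": "ABC", "D": "D"},
}


def run_task(
    matrix: np.ndarray,
    labels: np.ndarray,
    task: str,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    stratify: bool = True,
) -> ClassificationReport:
    """Run one named classification task (ABCD, ACD or ABCvD) end to end.

    Z-scoring is fit on the full (task-restricted) table before
    cross-validation.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {list(TASKS)}")
    spec = TASKS[task]
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if spec is not None:
        keep, labels = merge_classes(labels, spec)
        x = x[keep]
    return cross_validated_svm(
        zscore(x), labels, k=k, seed=seed, C=C, task=task, stratify=stratify
    )
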