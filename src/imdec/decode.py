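"""Core MVPA: F-selection, one-vs-one linear SVM voting, leave-one-run-out
cross-validation, and scrambled-label permutation inference.

Within every cross-validation fold the ANOVA-F feature ranking and the
top-k selection are computed on the training runs only, so no information
from the held-out run leaks into the feature set.  Class prediction uses
C(4,2) = 6 binary linear soft-margin SVMs with majority voting; vote ties
go to the lowest class label.  The permutation test reruns the *full*
pipeline (including fold-wise selection) under scrambled labels and uses
the add-one Monte-Carlo p-value.

Model/Results surface: :class:`DirectionDecoder` is built from a
:class:`~imdec.containers.TrialFeatureMatrix`; :meth:`DirectionDecoder.fit`
returns a :class:`DecodingResult`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.svm import SVC

from .containers import TrialFeatureMatrix

__all__ = [
    "anova_f",
    "select_top_k",
    "majority_vote",
    "train_predict_ovo",
    "cross_validate",
    "permutation_test",
    "permutation_p",
    "DirectionDecoder",
    "DecodingResult",
]


def anova_f(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per voxel: between/within class variance ratio.

    Vectorised over columns of ``values`` (trials x voxels).  Voxels with
    zero within-class variance get +inf when the between-class sum of
    squares is positive (maximal evidence) and 0.0 when it is zero
    (totally constant voxel).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least 2 classes in the training data")
    n = len(labels)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 training trials")
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for c in classes:
        sub = values[labels == c]
        m = sub.mean(axis=0)
        ssb += len(sub) * (m - grand) ** 2
        ssw += ((sub - m) ** 2).sum(axis=0)
    df_b = len(classes) - 1
    df_w = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f[(ssw == 0) & (ssb > 0)] = np.inf
    f[(ssw == 0) & (ssb == 0)] = 0.0
    return f


def select_top_k(scores: np.ndarray, k: int = 1000) -> np.ndarray:
    """Indices of the k highest-F voxels, sorted ascending.

    Infinite scores rank above all finite ones; ties at the cutoff are
    broken by ascending voxel index, so the selection is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if k > n:
        raise ValueError(
            f"cannot select k={k} voxels from {n}; lower k to at most {n}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    # primary key: descending score; secondary: ascending index
    order = np.lexsort((np.arange(n), -scores))
    return np.sort(order[:k])


def majority_vote(votes: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Predicted class per row of a (trials x classes) vote-count matrix.

    Ties are broken by the lowest class label (``classes`` must be sorted
    ascending; ``argmax`` returns the first maximum).
    """
    classes = np.asarray(classes)
    return classes[np.argmax(votes, axis=1)]


def train_predict_ovo(
    train: TrialFeatureMatrix,
    test: TrialFeatureMatrix,
    C: float = 1.0,
) -> np.ndarray:
    """One-vs-one multiclass prediction with binary linear SVMs.

    Fits one soft-margin linear SVM per class pair on the training trials
    and predicts each test trial by majority vote over the 6 binary
    decisions (for 4 classes).  Train and test must share voxel columns.
    """
    if train.n_voxels != test.n_voxels or not np.array_equal(
        train.voxel_index, test.voxel_index
    ):
        raise ValueError("train and test feature matrices must share voxel columns")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    votes = np.zeros((test.n_trials, len(classes)), dtype=int)
    col = {c: i for i, c in enumerate(classes)}
    for a, b in combinations(classes, 2):
        sel = (train.labels == a) | (train.labels == b)
        clf = SVC(kernel="linear", C=C)
        clf.fit(train.values[sel], train.labels[sel])
        pred = clf.predict(test.values)
        for c in (a, b):
            votes[pred == c, col[c]] += 1
    return majority_vote(votes, classes)


@dataclass
class DecodingResult:
    """Cross-validated decoding performance, optionally with its null.

    ``fold_accuracies`` holds the proportion correct per leave-one-run-out
    fold; ``confusion`` pools true x predicted counts over all folds.
    After a permutation test, ``null_accuracies`` holds the scrambled-label
    mean accuracies, ``p_value`` the add-one Monte-Carlo probability and
    ``null_95th`` the null distribution's 95th percentile.
    """

    fold_accuracies: np.ndarray
    confusion: np.ndarray
    classes: np.ndarray
    fold_runs: np.ndarray
    selected_per_fold: list[np.ndarray] = field(default_factory=list, repr=False)
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    null_95th: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def n_trials(self) -> int:
        return int(self.confusion.sum())

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def summary(self) -> str:
        lines = [
            "Leave-one-run-out decoding",
            f"  folds (held-out runs):   {[int(r) for r in self.fold_runs]}",
            "  fold accuracies:         "
            + ", ".join(f"{a:.3f}" for a in self.fold_accuracies),
            f"  mean accuracy:           {self.mean_accuracy:.4f}",
            f"  chance level:            {1.0 / len(self.classes):.4f}",
            f"  pooled trials:           {self.n_trials}",
        ]
        if self.null_accuracies is not None:
            lines += [
                f"  permutations:            {len(self.null_accuracies)}",
                f"  null mean accuracy:      {float(np.mean(self.null_accuracies)):.4f}",
                f"  null 95th percentile:    {self.null_95th:.4f}",
                f"  p (add-one Monte Carlo): {self.p_value:.6g}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "fold_runs": [int(r) for r in self.fold_runs],
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "classes": [int(c) for c in self.classes],
            "confusion": self.confusion.astype(int).tolist(),
        }
        if self.null_accuracies is not None:
            d["n_perm"] = len(self.null_accuracies)
            d["null_mean"] = float(np.mean(self.null_accuracies))
            d["null_95th"] = float(self.null_95th)
            d["p_value"] = float(self.p_value)
            d["null_accuracies"] = [float(a) for a in self.null_accuracies]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def plot_null(self, ax=None):
        """Histogram of the permutation null with the observed accuracy."""
        if self.null_accuracies is None:
            raise ValueError("no permutation null attached to this result")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_accuracies, bins=30, color="0.7", label="null")
        ax.axvline(self.mean_accuracy, color="C3", label="observed")
        ax.axvline(self.null_95th, color="0.3", ls="--", label="null 95th")
        ax.set_xlabel("mean CV accuracy")
        ax.set_ylabel("count")
        ax.legend()
        return ax


def _check_runs_have_all_classes(features: TrialFeatureMatrix) -> None:
    classes = features.classes
    for r in np.unique(features.runs):
        present = np.unique(features.labels[features.runs == r])
        missing = np.setdiff1d(classes, present)
        if len(missing):
            raise ValueError(f"run {r} is missing class(es) {list(missing)}")


def cross_validate(
    features: TrialFeatureMatrix,
    n_features: int | None = 1000,
    C: float = 1.0,
) -> DecodingResult:
    """Leave-one-run-out cross-validation with fold-wise feature selection.

    One fold per run.  Within each fold the ANOVA-F scores and the top-k
    selection are computed on the training trials only, then the one-vs-one
    SVM ensemble predicts the held-out run.  ``n_features=None`` disables
    selection (as in the searchlight analysis).
    """
    runs = np.unique(features.runs)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    _check_runs_have_all_classes(features)
    classes = features.classes

    fold_acc = []
    selected_per_fold = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for held_out in runs:
        train_m = features.runs != held_out
        test_m = ~train_m
        train_vals = features.values[train_m]
        train_lab = features.labels[train_m]
        if n_features is not None:
            f = anova_f(train_vals, train_lab)
            cols = select_top_k(f, n_features)
        else:
            cols = np.arange(features.n_voxels)
        selected_per_fold.append(cols)
        sub = features.select_voxels(cols)
        train = TrialFeatureMatrix(
            sub.values[train_m], train_lab, features.runs[train_m], sub.voxel_index
        )
        test = TrialFeatureMatrix(
            sub.values[test_m], features.labels[test_m], features.runs[test_m],
            sub.voxel_index,
        )
        pred = train_predict_ovo(train, test, C=C)
        fold_acc.append(float(np.mean(pred == test.labels)))
        pooled += _sk_confusion(test.labels, pred, labels=classes)
    return DecodingResult(
        fold_accuracies=np.asarray(fold_acc),
        confusion=pooled,
        classes=classes,
        fold_runs=runs,
        selected_per_fold=selected_per_fold,
    )


def permutation_p(observed: float, null: np.ndarray) -> float:
    """Add-one Monte-Carlo p: (1 + #{null >= observed}) / (n_perm + 1)."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def _scramble(labels: np.ndarray, runs: np.ndarray, rng: np.random.Generator,
              scheme: str) -> np.ndarray:
    if scheme == "global":
        return rng.permutation(labels)
    if scheme == "within_run":
        out = labels.copy()
        for r in np.unique(runs):
            m = runs == r
            out[m] = rng.permutation(labels[m])
        return out
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_test(
    features: TrialFeatureMatrix,
    n_features: int | None = 1000,
    C: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "global",
) -> DecodingResult:
    """Scrambled-label permutation test around the full CV pipeline.

    Each of the ``n_perm`` repetitions permutes the labels (globally by
    default, preserving class counts; ``scheme="within_run"`` keeps the
    per-run label multisets intact) and reruns the complete
    cross-validation including fold-wise feature selection.  The add-one
    p-value and the null's 95th percentile are attached to the observed
    result.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = cross_validate(features, n_features=n_features, C=C)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = _scramble(features.labels, features.runs, rng, scheme)
        res = cross_validate(features.with_labels(perm), n_features=n_features, C=C)
        null[i] = res.mean_accuracy
    observed.null_accuracies = null
    observed.p_value = permutation_p(observed.mean_accuracy, null)
    observed.null_95th = float(np.percentile(null, 95))
    return observed


class DirectionDecoder:
    """Four-class motion-direction decoder over a trial feature matrix.

    Parameters
    ----------
    features : TrialFeatureMatrix
        Trials x voxels in z-units with labels and run ids.
    n_features : int or None
        Voxels retained per fold by ANOVA-F selection (None = keep all).
    C : float
        Soft-margin regularisation constant of the binary SVMs.
    scheme : str
        Label-scrambling scheme for the permutation test
        (``"global"`` or ``"within_run"``).
    """

    def __init__(
        self,
        features: TrialFeatureMatrix,
        n_features: int | None = 1000,
        C: float = 1.0,
        scheme: str = "global",
    ):
        self.features = features
        self.n_features = n_features
        self.C = C
        self.scheme = scheme

    def fit(self, n_perm: int = 0, seed: int | None = None) -> DecodingResult:
        """Cross-validate; with ``n_perm > 0`` also run the permutation test."""
        if n_perm:
            return permutation_test(
                self.features, n_features=self.n_features, C=self.C,
                n_perm=n_perm, seed=seed, scheme=self.scheme,
            )
        return cross_validate(self.features, n_features=self.n_features, C=self.C)
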