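"""Candidate-panel evaluation: cross-validated subtype classification,
panel-growth trajectories, subtype stratification t-tests, and clustering
leaf order.

Classification targets are the four receptor-based subtype classes of the
tumor samples (HR+HER2−, HR+HER2+, HR−HER2+, TNG).  Any object with a
``fit(X, y)`` / ``predict(X)`` contract can serve as the classifier; the
native reference implementation is a k-nearest-neighbor voter (k = 10 by
default) with deterministic tie-breaking, so leave-one-out accuracy is a
single number while k-fold accuracy varies only through fold reshuffling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold


def knn_predict(train_matrix, train_labels, test_vector, k: int = 10):
    """Label of ``test_vector`` by majority vote of its k nearest training
    samples (Euclidean distance).

    Distance ties break by training-sample order; vote ties break by the
    class of the nearest neighbor among the tied classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_labels)
    if k > len(y):
        raise ValueError(f"k={k} exceeds training size {len(y)}")
    d = np.linalg.norm(x - np.asarray(test_vector, dtype=float), axis=1)
    order = np.lexsort((np.arange(len(d)), d))  # stable in sample order
    nearest = order[:k]
    votes = Counter(y[nearest])
    top = max(votes.values())
    tied = {cls for cls, v in votes.items() if v == top}
    if len(tied) == 1:
        return tied.pop()
    for idx in nearest:
        if y[idx] in tied:
            return y[idx]
    raise AssertionError("unreachable: some tied class has a neighbor")


class KNNClassifier:
    """Native k-nearest-neighbor classifier (fit/predict contract).

    Deterministic: no randomness enters prediction, so repeated leave-one-out
    runs collapse to a single value.
    """

    deterministic = True

    def __init__(self, k: int = 10):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.name = f"knn{k}"

    def fit(self, X, y):
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(self.k, len(self._y))
        return np.array([knn_predict(self._X, self._y, row, k) for row in X])


@dataclass
class CVReport:
    """Accuracy summary of repeated cross-validation for one panel/cohort."""

    panel: tuple
    dataset: str
    scheme: str
    classifier: str
    accuracies: np.ndarray = field(repr=False)
    collapsed: bool = False  # deterministic classifier under LOO: one value

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    def to_row(self) -> dict:
        return {
            "panel": ";".join(self.panel),
            "dataset": self.dataset,
            "scheme": self.scheme,
            "classifier": self.classifier,
            "repeats": len(self.accuracies),
            "collapsed": self.collapsed,
            "median": self.median,
            "mean": self.mean,
            "max": self.max,
            "min": self.min,
        }


def _panel_matrix(dataset, panel):
    panel = [str(g).upper() for g in panel]
    missing = [g for g in panel if g not in dataset.values.index]
    if missing:
        raise KeyError(f"panel genes absent from {dataset.name}: {missing}")
    tumors = dataset.tumor_samples
    X = dataset.values.loc[panel, tumors].to_numpy(dtype=float).T
    y = dataset.subtypes().loc[tumors].to_numpy()
    return panel, X, y


def _loo_accuracy(X, y, classifier) -> float:
    correct = 0
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        classifier.fit(X[mask], y[mask])
        correct += classifier.predict(X[i : i + 1])[0] == y[i]
    return correct / len(y)


def _kfold_accuracy(X, y, classifier, n_splits: int, rep_seed: int) -> float:
    counts = Counter(y)
    if min(counts.values()) < 2:
        raise ValueError(f"class with < 2 samples under k-fold: {counts}")
    n_splits = min(n_splits, min(counts.values()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rep_seed)
    correct = 0
    for train, test in skf.split(X, y):
        classifier.fit(X[train], y[train])
        correct += int((classifier.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def cross_validate(
    dataset,
    panel,
    scheme: str = "kfold10",
    classifier=None,
    repeats: int = 1000,
    seed: int | None = None,
) -> CVReport:
    """Repeated cross-validation of a gene panel on one cohort's tumor
    samples, classifying the four subtype classes.

    ``scheme`` is ``'loo'`` (leave-one-out) or ``'kfold10'`` (stratified
    10-fold, folds reshuffled each repeat).  With a deterministic classifier
    leave-one-out has nothing to repeat: the report collapses to the single
    value and is flagged ``collapsed``.
    """
    if scheme not in ("loo", "kfold10"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    classifier = classifier or KNNClassifier(k=10)
    panel, X, y = _panel_matrix(dataset, panel)
    rng = np.random.default_rng(seed)
    deterministic = getattr(classifier, "deterministic", False)
    collapsed = False
    if scheme == "loo":
        if deterministic:
            acc = np.array([_loo_accuracy(X, y, classifier)])
            collapsed = repeats > 1
        else:
            acc = np.array([_loo_accuracy(X, y, classifier) for _ in range(repeats)])
    else:
        rep_seeds = rng.integers(0, 2**31 - 1, size=repeats)
        acc = np.array(
            [_kfold_accuracy(X, y, classifier, 10, int(s)) for s in rep_seeds]
        )
    return CVReport(
        panel=tuple(panel),
        dataset=dataset.name,
        scheme=scheme,
        classifier=getattr(classifier, "name", type(classifier).__name__),
        accuracies=acc,
        collapsed=collapsed,
    )


def panel_trajectory(
    dataset,
    ranked_genes,
    scheme: str = "kfold10",
    classifier=None,
    repeats: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy of every prefix of a ranked gene list (panel growth)."""
    ranked = [str(g).upper() for g in ranked_genes]
    if not ranked:
        raise ValueError("ranked gene list is empty")
    rows = []
    for size in range(1, len(ranked) + 1):
        report = cross_validate(
            dataset, ranked[:size], scheme, classifier, repeats=repeats, seed=seed
        )
        rows.append(
            {
                "size": size,
                "added_gene": ranked[size - 1],
                "mean_accuracy": report.mean,
                "median_accuracy": report.median,
            }
        )
    return pd.DataFrame(rows).set_index("size")


def stratify_t(dataset, gene, grouping: str = "ER"):
    """Pooled-variance Student t test of one gene between subtype strata.

    ``grouping='ER'`` contrasts ER+ vs ER− tumors; ``grouping='TNG'``
    contrasts the triple-negative group against all other tumors.  Returns
    ``(t, p)`` with a two-sided p.
    """
    gene = str(gene).upper()
    if gene not in dataset.values.index:
        raise KeyError(f"gene absent from {dataset.name}: {gene}")
    tumors = dataset.tumor_samples
    annot = dataset.annotations.loc[tumors]
    if grouping == "ER":
        in_a = annot["ER"] == "+"
    elif grouping == "TNG":
        in_a = dataset.subtypes().loc[tumors] == "TNG"
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    a = dataset.values.loc[gene, annot.index[in_a]].to_numpy(dtype=float)
    b = dataset.values.loc[gene, annot.index[~in_a]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"degenerate strata for {grouping}: {len(a)} vs {len(b)}")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cluster_order(
    dataset,
    panel,
    distance: str = "euclidean",
    linkage: str = "average",
):
    """Agglomerative clustering of samples on the panel-restricted matrix.

    Returns ``(leaf_order, merge_tree)``: the ordered sample ids of the
    dendrogram leaves and the scipy linkage matrix.  ``distance`` is
    ``euclidean`` or ``correlation``; ``linkage`` is ``average``,
    ``complete`` or ``ward`` (ward requires euclidean distance).
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance: {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    panel = [str(g).upper() for g in panel]
    X = dataset.values.loc[panel].to_numpy(dtype=float).T
    samples = dataset.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(X, metric=distance)
    tree = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(tree)
    return [samples[i] for i in order], tree
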