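"""SVM classification of memory-load state from node-importance vectors.

One epoch's network yields one feature vector: the per-node importance
scores (WKPN Q, node strength, or PageRank), aligned to the canonical
montage.  An RBF-kernel SVM separates the two load states on repeated
stratified 3:2 train:test splits.  Feature standardization and, when a
reduced feature length m < n is requested, the choice of the top-m nodes
are computed on each training fold only — never on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .wkpn import ImportanceProfile

__all__ = ["StateDataset", "EvalReport", "build_features", "evaluate",
           "length_sweep", "compare_methods"]


@dataclass
class StateDataset:
    """Labeled node-importance feature vectors for one band and method.

    ``X`` holds the full per-node feature matrix (samples x nodes, in
    canonical node order); ``n_features`` <= n nodes requests top-m node
    selection at evaluation time.
    """

    X: np.ndarray
    y: np.ndarray
    node_labels: tuple[str, ...]
    band: str | None = None
    method: str = "wkpn"
    n_features: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x nodes)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("label count does not match sample count")
        if self.X.shape[1] != len(self.node_labels):
            raise ValueError("node label count does not match X columns")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        if self.n_features is not None and not (
                1 <= self.n_features <= self.X.shape[1]):
            raise ValueError("n_features out of range")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class EvalReport:
    """Accuracy of one classifier evaluation over repeated random splits."""

    accuracies: np.ndarray
    split_ratio: str
    n_repetitions: int
    seed: int
    method: str = "wkpn"
    band: str | None = None
    n_features: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def build_features(profiles: list[ImportanceProfile],
                   labels: list[str],
                   m: int | None = None,
                   band: str | None = None,
                   method: str = "wkpn") -> StateDataset:
    """Assemble a StateDataset from per-epoch importance profiles.

    All profiles must share the montage; features follow canonical node
    order.  ``m`` requests top-m feature selection (performed on training
    folds during evaluation, to avoid test-set leakage).
    """
    if not profiles:
        raise ValueError("no profiles given")
    ref = profiles[0].node_labels
    for p in profiles[1:]:
        if p.node_labels != ref:
            raise ValueError("profiles use mixed montages")
    X = np.vstack([p.Q for p in profiles])
    return StateDataset(X=X, y=np.asarray(labels), node_labels=ref,
                        band=band, method=method, n_features=m)


def _make_svm() -> object:
    # RBF kernel, C = 1, gamma = 1/(m * feature variance) ("scale")
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0,
                                               gamma="scale"))


def evaluate(ds: StateDataset, n_repetitions: int = 20, seed: int = 0,
             test_size: float = 0.4,
             selection: str = "train_only") -> EvalReport:
    """Repeated stratified 3:2 split evaluation of an RBF SVM.

    For each repetition the samples are randomly split 3:2 (stratified so
    both classes appear on both sides), features are standardized on the
    training fold, the SVM is fit, and test accuracy recorded.  When the
    dataset requests m < n features, the top-m nodes are picked by mean
    feature value over the *training fold* (``selection="train_only"``,
    default) or over all samples (``"global"``).

    Deterministic for a fixed seed.
    """
    classes, counts = np.unique(ds.y, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need >= 10 samples per class")
    if selection not in ("train_only", "global"):
        raise ValueError(f"unknown selection {selection!r}")
    m = ds.n_features
    splitter = StratifiedShuffleSplit(n_splits=n_repetitions,
                                      test_size=test_size,
                                      random_state=seed)
    global_cols = None
    if m is not None and selection == "global":
        global_cols = np.argsort(-ds.X.mean(axis=0), kind="stable")[:m]

    accs = []
    for train, test in splitter.split(ds.X, ds.y):
        X_tr, X_te = ds.X[train], ds.X[test]
        if m is not None:
            cols = (global_cols if global_cols is not None else
                    np.argsort(-X_tr.mean(axis=0), kind="stable")[:m])
            X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        clf = _make_svm()
        clf.fit(X_tr, ds.y[train])
        accs.append(float(clf.score(X_te, ds.y[test])))
    return EvalReport(accuracies=np.array(accs), split_ratio="3:2",
                      n_repetitions=n_repetitions, seed=seed,
                      method=ds.method, band=ds.band, n_features=m,
                      meta={"selection": selection})


def length_sweep(ds: StateDataset, lengths: list[int],
                 n_repetitions: int = 20, seed: int = 0,
                 selection: str = "train_only") -> dict:
    """Accuracy as a function of feature-vector length.

    Every length is evaluated with the same seed, hence identical splits;
    returns the accuracy curve and the best length (smallest argmax).
    """
    n = len(ds.node_labels)
    if any(not 1 <= m <= n for m in lengths):
        raise ValueError("lengths must lie in [1, n]")
    reports = {}
    for m in lengths:
        sub = StateDataset(X=ds.X, y=ds.y, node_labels=ds.node_labels,
                           band=ds.band, method=ds.method, n_features=m)
        reports[m] = evaluate(sub, n_repetitions=n_repetitions, seed=seed,
                              selection=selection)
    curve = {m: r.mean_accuracy for m, r in reports.items()}
    best = max(curve, key=lambda m: (curve[m], -m))
    return {"curve": curve, "best_length": best, "reports": reports}


def compare_methods(datasets: dict[str, StateDataset],
                    n_repetitions: int = 20,
                    seed: int = 0) -> dict[str, EvalReport]:
    """Evaluate several ranking methods on identical splits.

    All datasets must describe the same epochs (equal sample counts and
    labels); the shared seed makes the split sequence identical across
    methods, so accuracy differences reflect the features alone.
    """
    items = list(datasets.items())
    ref = items[0][1]
    for name, ds in items[1:]:
        if ds.n_samples != ref.n_samples or not np.array_equal(ds.y, ref.y):
            raise ValueError(
                f"dataset {name!r} does not match the others "
                "(sample count or labels differ)")
    return {name: evaluate(ds, n_repetitions=n_repetitions, seed=seed)
            for name, ds in items}
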