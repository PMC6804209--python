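"""PCA dimension reduction and 1-nearest-neighbor classification.

PCA keeps the smallest number of components explaining a variance
threshold (default 95%); classification is k-nearest-neighbor in score
space (k = 1, Euclidean distance, equal weights) evaluated with a
stratified 25% holdout.  Ties at exactly equal distances resolve to the
lowest training index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import LabeledSpectrumSet

__all__ = [
    "PCAModel",
    "KNNModel",
    "ClassificationReport",
    "fit_pca",
    "n_components_for_variance",
    "project",
    "reconstruct",
    "stratified_holdout_split",
    "knn_classify",
    "evaluate",
    "holdout_classification",
]


@dataclass(frozen=True)
class PCAModel:
    """Mean spectrum + orthonormal loadings + explained-variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_channels), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_channels(self) -> int:
        return self.components.shape[1]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, LabeledSpectrumSet):
        return data.intensities
    return np.asarray(data, dtype=float)


def fit_pca(data) -> PCAModel:
    """Full mean-centered PCA via SVD.

    Sign convention: each loading's largest-magnitude coefficient is made
    positive, so scores are reproducible across backends.
    """
    X = _as_matrix(data)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    # deterministic sign: largest |coefficient| of each loading positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    return PCAModel(
        mean=mean,
        components=Vt * signs[:, None],
        explained_variance=var,
        explained_variance_ratio=ratio,
    )


def n_components_for_variance(model_or_ratios, threshold: float = 0.95) -> int:
    """Smallest m with cumulative explained-variance ratio >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(model_or_ratios, PCAModel):
        ratios = model_or_ratios.explained_variance_ratio
    else:
        ratios = np.asarray(model_or_ratios, dtype=float)
    cum = np.cumsum(ratios)
    # tolerate float round-off at exact thresholds (e.g. 0.76 vs 0.76)
    hits = np.nonzero(cum >= threshold - 1e-12)[0]
    if hits.size == 0:
        return int(np.count_nonzero(ratios))
    return int(hits[0]) + 1


def project(model: PCAModel, data) -> np.ndarray:
    """Scores = (X - mean) @ loadings^T; the training mean maps to 0."""
    X = _as_matrix(data)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: {X.shape[1]} != {model.n_channels}"
        )
    scores = (X - model.mean) @ model.components.T
    return scores[0] if single else scores


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return scores @ model.components + model.mean


def stratified_holdout_split(dataset: LabeledSpectrumSet,
                             fraction: float = 0.25,
                             level: str = "spectrum",
                             seed: int = 0):
    """Seeded stratified (or biopsy-grouped) train/test split.

    ``level="spectrum"`` holds out round(fraction * n) spectra per class;
    ``level="biopsy"`` holds out whole biopsies per class until the
    held-out spectrum count reaches the fraction, so no biopsy id spans
    both partitions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if level not in ("spectrum", "biopsy"):
        raise ValueError("level must be 'spectrum' or 'biopsy'")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in np.unique(dataset.labels):
        idx = np.nonzero(dataset.labels == cls)[0]
        if level == "spectrum":
            if idx.size < 2:
                raise ValueError(f"class {cls!r} needs >= 2 spectra to split")
            n_test = int(round(fraction * idx.size))
            n_test = min(max(n_test, 1), idx.size - 1)
            perm = rng.permutation(idx)
            test_idx.extend(perm[:n_test])
            train_idx.extend(perm[n_test:])
        else:
            if dataset.biopsy_ids is None:
                raise ValueError("biopsy-level split needs biopsy_ids")
            groups = np.unique(dataset.biopsy_ids[idx])
            if groups.size < 2:
                raise ValueError(
                    f"class {cls!r} has a single biopsy; cannot split at "
                    "biopsy level"
                )
            perm = rng.permutation(groups)
            target = fraction * idx.size
            held: set = set()
            count = 0
            for g in perm[:-1]:  # always keep >= 1 biopsy for training
                if count >= target:
                    break
                held.add(g)
                count += int((dataset.biopsy_ids[idx] == g).sum())
            for i in idx:
                (test_idx if dataset.biopsy_ids[i] in held else train_idx).append(i)
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


@dataclass(frozen=True)
class KNNModel:
    """Training scores + labels; Euclidean metric, equal weights."""

    scores: np.ndarray
    labels: np.ndarray
    k: int = 1

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 2 or scores.shape[0] == 0:
            raise ValueError("training scores must be a non-empty 2-D array")
        if labels.shape != (scores.shape[0],):
            raise ValueError("one label per training score required")
        if not 1 <= self.k <= scores.shape[0]:
            raise ValueError("k must satisfy 1 <= k <= n_train")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)


def knn_classify(model: KNNModel, queries: np.ndarray) -> np.ndarray:
    """Predict labels for query scores.

    For k = 1, the label of the Euclidean-nearest training point; exact
    distance ties resolve to the lowest training index.  For k > 1,
    majority vote among the k nearest (neighbor order by distance then
    index), ties between classes resolved by the nearest member.
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.scores.shape[1]:
        raise ValueError("query dimensionality does not match training scores")
    d = cdist(Q, model.scores)
    if model.k == 1:
        return model.labels[np.argmin(d, axis=1)]  # argmin -> lowest index
    preds = []
    for row in d:
        order = np.lexsort((np.arange(row.size), row))[: model.k]
        neigh = model.labels[order]
        uniq, counts = np.unique(neigh, return_counts=True)
        best = counts.max()
        tied = set(uniq[counts == best])
        for lab in neigh:  # nearest member of a tied class wins
            if lab in tied:
                preds.append(lab)
                break
    return np.asarray(preds)


@dataclass
class ClassificationReport:
    """Confusion matrix plus per-class recall and overall accuracy."""

    classes: np.ndarray
    confusion: np.ndarray  # rows: true class, cols: predicted class
    per_class_accuracy: dict
    overall_accuracy: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": {
                str(k): float(v) for k, v in self.per_class_accuracy.items()
            },
            "overall_accuracy": float(self.overall_accuracy),
            "metadata": dict(self.metadata),
        }


def evaluate(true_labels, predicted_labels, metadata: dict | None = None
             ) -> ClassificationReport:
    """Confusion matrix, per-class accuracy (recall) and overall accuracy."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("true and predicted label arrays must match")
    if y.size == 0:
        raise ValueError("no labels to evaluate")
    classes = np.unique(y)
    if not np.any(np.isin(p, classes)):
        raise ValueError("predicted labels share no class with true labels")
    index = {c: i for i, c in enumerate(classes)}
    extra = [c for c in np.unique(p) if c not in index]
    cols = list(classes) + extra
    col_index = {c: j for j, c in enumerate(cols)}
    cm = np.zeros((classes.size, len(cols)), dtype=int)
    for t, q in zip(y, p):
        cm[index[t], col_index[q]] += 1
    per_class = {
        c: cm[i, col_index[c]] / cm[i].sum() for i, c in enumerate(classes)
    }
    overall = sum(cm[i, col_index[c]] for i, c in enumerate(classes)) / y.size
    return ClassificationReport(
        classes=np.asarray(cols),
        confusion=cm,
        per_class_accuracy=per_class,
        overall_accuracy=float(overall),
        metadata=metadata or {},
    )


def holdout_classification(dataset: LabeledSpectrumSet,
                           variance_threshold: float = 0.95,
                           fraction: float = 0.25,
                           level: str = "spectrum",
                           k: int = 1,
                           seed: int = 0) -> ClassificationReport:
    """Split -> PCA on the training part -> keep components at the variance
    threshold -> 1-NN on scores -> report on the held-out part."""
    train, test = stratified_holdout_split(dataset, fraction, level, seed)
    pca = fit_pca(train)
    m = n_components_for_variance(pca, variance_threshold)
    train_scores = project(pca, train)[:, :m]
    test_scores = project(pca, test)[:, :m]
    knn = KNNModel(scores=train_scores, labels=train.labels, k=k)
    predictions = knn_classify(knn, test_scores)
    return evaluate(
        test.labels, predictions,
        metadata={
            "n_components": m,
            "variance_threshold": variance_threshold,
            "holdout_fraction": fraction,
            "split_level": level,
            "k": k,
            "seed": seed,
            "n_train": train.n_spectra,
            "n_test": test.n_spectra,
        },
    )
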