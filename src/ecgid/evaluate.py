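"""Closed-set identification evaluation: splits, confusion counts, FAR/FRR/K.

Metric definitions (closed-set, N enrolled users):

* accuracy — trace of the confusion matrix over the probe total;
* FRR (false rejection rate) — the fraction of genuine probes not credited
  to their own identity (with no rejection threshold this is 1 - accuracy);
* FAR (false acceptance rate) — macro average over identities i of the rate
  at which probes of *other* users are accepted as i:
  ``mean_i [ sum_{j != i} confusion[j, i] / sum_{j != i} row_total_j ]``;
* K — the ratio FRR / FAR (K * FAR = FRR), undefined (None) when FAR = 0.

For balanced classes and pure argmax decisions FAR = FRR / (C - 1) exactly,
so K = C - 1 whenever at least one probe is misclassified.

An optional probability threshold ``tau`` adds a reject option: probes whose
top probability falls below ``tau`` are rejected (counted as false
rejections, excluded from the false-accept counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ValidationError
from .io import GAFDataset
from .model import TrainedModel, predict

__all__ = [
    "DatasetSplit",
    "EvalReport",
    "split_dataset",
    "confusion_matrix",
    "identification_metrics",
    "k_ratio",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class DatasetSplit:
    """Train/validation/test fractions (default 80/10/10, stratified)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train <= 0 or self.test <= 0 or self.val < 0:
            raise ValidationError("train/test fractions must be positive (val may be 0)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


@dataclass
class EvalReport:
    """Confusion counts plus closed-set identification metrics."""

    confusion: np.ndarray
    class_order: np.ndarray
    accuracy: float
    per_class_accuracy: np.ndarray
    frr: float
    far: float
    k: float | None
    reject_threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": [str(c) for c in self.class_order],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "FRR": self.frr,
            "FAR": self.far,
            "K": self.k,
            "reject_threshold": self.reject_threshold,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def split_dataset(
    dataset: GAFDataset, split: DatasetSplit | None = None
) -> tuple[GAFDataset, GAFDataset, GAFDataset]:
    """Partition a dataset into train/val/test (deterministic given the seed).

    Stratified mode splits each class separately so class proportions are
    preserved to within one image; every class must have at least as many
    images as there are non-empty splits.
    """
    if split is None:
        split = DatasetSplit()
    rng = np.random.default_rng(split.seed)
    n = len(dataset)
    if n == 0:
        raise ValidationError("cannot split an empty dataset")

    def allocate(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = indices.size
        n_splits = 2 + (split.val > 0)
        if split.stratified and m < n_splits:
            raise ValidationError(
                f"a class has {m} images; at least {n_splits} are required "
                "for a stratified split"
            )
        perm = rng.permutation(indices)
        n_train = int(round(split.train * m))
        n_val = int(round(split.val * m))
        # every non-empty split keeps at least one image
        n_train = max(1, min(n_train, m - (1 + (split.val > 0))))
        if split.val > 0:
            n_val = max(1, min(n_val, m - n_train - 1))
        return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]

    if split.stratified:
        tr, va, te = [], [], []
        for cls in dataset.classes:
            a, b, c = allocate(np.flatnonzero(dataset.labels == cls))
            tr.append(a)
            va.append(b)
            te.append(c)
        idx_tr, idx_va, idx_te = (np.concatenate(p) for p in (tr, va, te))
    else:
        idx_tr, idx_va, idx_te = allocate(np.arange(n))
    return dataset.subset(idx_tr), dataset.subset(idx_va), dataset.subset(idx_te)


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, class_order: np.ndarray
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    class_order = np.asarray(class_order)
    if true_labels.shape != predicted_labels.shape:
        raise ValidationError("label vectors must have equal length")
    known = set(class_order.tolist())
    for vec, name in ((true_labels, "true"), (predicted_labels, "predicted")):
        unknown = set(np.unique(vec).tolist()) - known
        if unknown:
            raise ValidationError(f"unknown {name} labels: {sorted(unknown)}")
    return _sk_confusion(true_labels, predicted_labels, labels=class_order)


def k_ratio(frr: float, far: float) -> float | None:
    """K = FRR / FAR (the paper's K * FAR = FRR); None when FAR is zero."""
    if far == 0:
        return None
    return frr / far


def identification_metrics(
    confusion: np.ndarray,
    tau: float | None = None,
    probabilities: np.ndarray | None = None,
    true_indices: np.ndarray | None = None,
) -> EvalReport:
    """Compute accuracy, per-class accuracy, FRR, FAR and K from counts.

    Without a threshold the matrix alone determines everything.  With
    ``tau`` the per-probe ``probabilities`` (and ``true_indices`` giving each
    probe's row in class order) are needed: probes whose top probability is
    below ``tau`` are rejected.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1] or confusion.size == 0:
        raise ValidationError("confusion matrix must be square and non-empty")
    if np.any(confusion < 0) or not np.issubdtype(confusion.dtype, np.integer):
        raise ValidationError("confusion matrix must hold non-negative integer counts")
    total = int(confusion.sum())
    if total == 0:
        raise ValidationError("confusion matrix must count at least one probe")
    c = confusion.shape[0]

    if tau is not None:
        if probabilities is None or true_indices is None:
            raise ValidationError("threshold mode needs probabilities and true_indices")
        probabilities = np.asarray(probabilities, dtype=np.float64)
        true_indices = np.asarray(true_indices, dtype=np.int64)
        accepted = probabilities.max(axis=1) >= tau
        pred = probabilities.argmax(axis=1)  # ties -> lowest class index
        counts = np.zeros((c, c), dtype=np.int64)
        np.add.at(counts, (true_indices[accepted], pred[accepted]), 1)
        row_totals = np.bincount(true_indices, minlength=c)
    else:
        counts = confusion.astype(np.int64)
        row_totals = counts.sum(axis=1)

    genuine_hits = np.diagonal(counts)
    accuracy = float(genuine_hits.sum()) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_totals > 0, genuine_hits / np.maximum(row_totals, 1), np.nan)
    frr = 1.0 - accuracy  # rejected-or-misclassified genuine probes

    impostor_pool = total - row_totals  # probes not of class i
    accepted_as_i = counts.sum(axis=0) - genuine_hits
    with np.errstate(invalid="ignore", divide="ignore"):
        far_per_class = np.where(impostor_pool > 0, accepted_as_i / np.maximum(impostor_pool, 1), 0.0)
    far = float(far_per_class.mean())
    return EvalReport(
        confusion=confusion.astype(np.int64),
        class_order=np.arange(c),
        accuracy=accuracy,
        per_class_accuracy=per_class,
        frr=float(frr),
        far=far,
        k=k_ratio(float(frr), far),
        reject_threshold=tau,
    )


def evaluate_pipeline(
    trained: TrainedModel, test_set: GAFDataset, tau: float | None = None
) -> EvalReport:
    """Predict -> argmax/threshold -> confusion -> metrics, with provenance."""
    if len(test_set) == 0:
        raise ValidationError("cannot evaluate on an empty test set")
    extra = set(np.unique(test_set.labels)) - set(trained.classes)
    if extra:
        raise ValidationError(f"test classes not enrolled in the model: {sorted(extra)}")
    probs = predict(trained, test_set.images)
    pred_labels = trained.classes[probs.argmax(axis=1)]
    conf = confusion_matrix(test_set.labels, pred_labels, trained.classes)
    true_idx = np.searchsorted(trained.classes, test_set.labels)
    report = identification_metrics(
        conf,
        tau=tau,
        probabilities=probs if tau is not None else None,
        true_indices=true_idx if tau is not None else None,
    )
    report.class_order = trained.classes
    report.provenance = {
        "n_test": len(test_set),
        "model_seed": trained.config.seed,
        "input_size": trained.config.input_size,
        "num_classes": trained.config.num_classes,
    }
    return report
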