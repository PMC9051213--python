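"""Test-error computation and soft-committee prediction over replicas.

A soft committee sums the raw output-unit values of Nc replicas of the same
architecture — trained on the same examples from different initial weights —
and takes the argmax over labels. Nc = 1 reduces to a plain argmax.
"""

from __future__ import annotations

import numpy as np


def soft_committee_predict(replica_outputs) -> int:
    """Predicted label from per-replica output vectors (each of length
    n_labels): argmax_j of sum_s a_{j,s}."""
    stack = np.atleast_2d(np.asarray(replica_outputs, dtype=np.float64))
    return int(np.argmax(stack.sum(axis=0)))


def soft_committee_predict_batch(replica_output_matrices) -> np.ndarray:
    """Predictions for a batch: each element of the list is one replica's
    (M, n_labels) output matrix."""
    stack = np.stack([np.asarray(o, dtype=np.float64) for o in replica_output_matrices])
    return stack.sum(axis=0).argmax(axis=1)


def test_error(predictions, labels) -> float:
    """Misclassification fraction in [0, 1]."""
    predictions = np.asarray(predictions).ravel()
    labels = np.asarray(labels).ravel()
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(predictions != labels))


def summarize_runs(errors) -> tuple[float, float]:
    """Mean and sample std (ddof=1) of per-run test errors across seeds."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size < 2:
        raise ValueError("need at least two runs to report a spread")
    return float(errors.mean()), float(errors.std(ddof=1))


def confusion_counts(predictions, labels, n_classes: int = 10) -> np.ndarray:
    """(n_classes, n_classes) matrix: rows true label, columns prediction."""
    predictions = np.asarray(predictions, dtype=np.int64).ravel()
    labels = np.asarray(labels, dtype=np.int64).ravel()
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (labels, predictions), 1)
    return mat
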