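"""k-nearest-neighbour classifiers for the two methods under comparison.

The modular method (MM) trains one small classifier per sensor; the
non-modular method (NMM) trains a single classifier on the concatenation
of every sensor's features.  Both use 1-NN with a fractional Minkowski
distance (exponent 0.5), which up-weights agreement on individual features
relative to the Euclidean metric.

Determinism: training rows are canonicalised (stable sort by row id) and
distance ties resolve to the lowest canonical row index, so predictions
never depend on the order training data was supplied in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeighbourModel",
    "train",
    "predict",
    "predict_trial",
    "zero_input_predict",
    "minkowski_power_sums",
]


def minkowski_power_sums(q: np.ndarray, x: np.ndarray, exponent: float) -> np.ndarray:
    """sum_f |q - x|^p for every (query, training) pair.

    This is the Minkowski distance raised to the p-th power — a monotone
    transform, so nearest-neighbour ordering is unchanged and the final
    root can be skipped.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.abs(q[:, None, :] - x[None, :, :]).__pow__(exponent).sum(axis=2)


@dataclass
class NeighbourModel:
    """Stored-exemplar k-NN model (defaults: 1 neighbour, exponent 0.5)."""

    features: np.ndarray
    labels: np.ndarray
    n_neighbours: int = 1
    distance_exponent: float = 0.5
    row_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite training features")
        if self.n_neighbours < 1:
            raise ValueError("n_neighbours must be >= 1")
        if self.row_ids is None:
            self.row_ids = np.arange(self.features.shape[0])
        order = np.argsort(np.asarray(self.row_ids), kind="stable")
        self.features = self.features[order]
        self.labels = self.labels[order]
        self.row_ids = np.asarray(self.row_ids)[order]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Predicted label per query row."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        if q.shape[1] != self.n_features:
            raise ValueError(
                f"query dimensionality {q.shape[1]} != model {self.n_features}"
            )
        d = minkowski_power_sums(q, self.features, self.distance_exponent)
        if self.n_neighbours == 1:
            return self.labels[np.argmin(d, axis=1)]
        out = []
        for row in d:
            nn = np.argsort(row, kind="stable")[: self.n_neighbours]
            lab = self.labels[nn]
            classes, counts = np.unique(lab, return_counts=True)
            out.append(classes[np.argmax(counts)])  # tie -> lowest class value
        return np.array(out)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    n_neighbours: int = 1,
    distance_exponent: float = 0.5,
    row_ids: np.ndarray | None = None,
) -> NeighbourModel:
    """Fit (store) a k-NN model; see :class:`NeighbourModel`."""
    return NeighbourModel(features, labels, n_neighbours, distance_exponent, row_ids)


def predict(model: NeighbourModel, queries: np.ndarray) -> np.ndarray:
    return model.predict(queries)


def modal_label(window_labels: np.ndarray) -> object:
    """Modal vote over window predictions; count ties resolve to the label
    of the latest window whose label is among the tied maxima."""
    lab = np.asarray(window_labels)
    classes, counts = np.unique(lab, return_counts=True)
    tied = set(classes[counts == counts.max()].tolist())
    if len(tied) == 1:
        return next(iter(tied))
    for v in lab[::-1]:
        val = v.item() if hasattr(v, "item") else v
        if val in tied:
            return val
    return lab[-1]


def predict_trial(model: NeighbourModel, window_features: np.ndarray) -> object:
    """Classify one trial from its per-window feature rows.

    Each window is classified independently; the trial-level label is the
    modal window label (ties -> latest window's label).
    """
    wf = np.atleast_2d(np.asarray(window_features, dtype=float))
    if wf.shape[0] == 0:
        raise ValueError("at least one window is required")
    return modal_label(model.predict(wf))


def zero_input_predict(
    combined: NeighbourModel,
    feature_row: np.ndarray,
    dropped_columns: np.ndarray | None = None,
) -> object:
    """NMM prediction under sensor dropout: the dropped sensors' feature
    columns are set to 0 and the row is classified with no further special
    handling — this is the combined classifier's dropout behaviour."""
    row = np.asarray(feature_row, dtype=float).copy()
    if dropped_columns is not None:
        row[np.asarray(dropped_columns, dtype=int)] = 0.0
    return combined.predict(row[None, :])[0]
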