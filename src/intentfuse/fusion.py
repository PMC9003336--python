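"""Confusion-matrix-weighted Bayesian fusion of per-sensor decisions.

Each sensor s carries a class-conditional confusion matrix
``P_s(predicted = j | true = i)`` estimated on held-out data.  Given the
set of currently active sensors and their (assumed conditionally
independent) predictions ``v_s``, the posterior over intent classes is

    P(c | v) ∝ P(c) * prod_s P_s(v_s | c)

normalised over classes — the multi-class form of binary Bayes fusion,
where the denominator's "event did not occur" term becomes the sum over
the competing classes.  Sensors drop in or out simply by adding or
removing their factor; nothing else is retrained.

Products are accumulated in log space so large networks cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassPrior",
    "FusionResult",
    "estimate_confusion",
    "sensor_accuracy",
    "fuse",
    "decide",
]


@dataclass
class ConfusionMatrix:
    """Row-stochastic class-conditional prediction probabilities.

    ``probs[i, j] = P(predicted = classes[j] | true = classes[i])``,
    derived from raw ``counts`` with additive (pseudo-count) smoothing:
    ``probs[i, j] = (counts[i, j] + s) / (row_i_total + C * s)``.
    An all-zero row with zero smoothing falls back to a uniform row.
    """

    sensor_id: str
    classes: tuple
    counts: np.ndarray
    smoothing: float = 1.0
    probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        row_tot = self.counts.sum(axis=1, keepdims=True)
        num = self.counts + self.smoothing
        den = row_tot + c * self.smoothing
        probs = np.empty_like(num)
        empty = den[:, 0] == 0
        probs[~empty] = num[~empty] / den[~empty]
        probs[empty] = 1.0 / c
        self.probs = probs

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def estimate_confusion(
    predictions, truths, classes, smoothing: float = 1.0, sensor_id: str = ""
) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a smoothed confusion matrix."""
    predictions = list(predictions)
    truths = list(truths)
    if not predictions or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be equal-length and non-empty")
    classes = tuple(classes)
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(truths, predictions):
        if t not in index:
            raise ValueError(f"truth label {t!r} not in class list")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class list")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(sensor_id, classes, counts, smoothing)


def sensor_accuracy(cm: ConfusionMatrix) -> float:
    """Balanced accuracy: trace of the row-stochastic matrix over C.

    Each diagonal entry is the per-class recall, so the trace divided by
    the class count is the mean per-class accuracy."""
    return float(np.trace(cm.probs) / cm.n_classes)


@dataclass(frozen=True)
class ClassPrior:
    classes: tuple
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.classes),):
            raise ValueError("one probability per class required")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("prior must be a probability distribution")
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform(cls, classes) -> "ClassPrior":
        classes = tuple(classes)
        return cls(classes, np.full(len(classes), 1.0 / len(classes)))


@dataclass
class FusionResult:
    classes: tuple
    posterior: np.ndarray
    decision: object
    active_sensors: frozenset
    predictions: dict


def fuse(
    predictions: dict,
    cms: dict[str, ConfusionMatrix],
    prior: ClassPrior,
) -> FusionResult:
    """Combine the active sensors' hard decisions into a class posterior.

    ``predictions`` maps each *active* sensor to its predicted class; every
    active sensor must have a confusion matrix over the same class list as
    the prior.  Inactive sensors are simply absent.  With no active sensor
    the posterior is the prior.  Decision ties resolve to the lowest class
    index.
    """
    classes = prior.classes
    index = {c: k for k, c in enumerate(classes)}
    with np.errstate(divide="ignore"):
        log_scores = np.log(prior.probabilities)
        # fixed accumulation order => exact permutation invariance
        for sid in sorted(predictions, key=str):
            pred = predictions[sid]
            if sid not in cms:
                raise KeyError(f"no confusion matrix for active sensor {sid!r}")
            cm = cms[sid]
            if cm.classes != classes:
                raise ValueError(
                    f"class-list mismatch between sensor {sid!r} and prior"
                )
            if pred not in index:
                raise ValueError(f"prediction {pred!r} not in class list")
            log_scores = log_scores + np.log(cm.probs[:, index[pred]])
    if np.all(np.isinf(log_scores) & (log_scores < 0)):
        raise ValueError(
            "all fused scores are zero; use smoothing > 0 on the confusion matrices"
        )
    log_scores = log_scores - log_scores.max()
    scores = np.exp(log_scores)
    posterior = scores / scores.sum()
    decision = classes[int(np.argmax(posterior))]
    return FusionResult(
        classes=classes,
        posterior=posterior,
        decision=decision,
        active_sensors=frozenset(predictions),
        predictions=dict(predictions),
    )


def decide(result: FusionResult) -> object:
    """The maximum-posterior class of a fusion result."""
    return result.decision
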