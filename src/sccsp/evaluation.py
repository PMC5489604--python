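"""Classification-quality and class-separability statistics.

Accuracy, Cohen's kappa (chance-corrected agreement), and the feature-space
separability statistics: within-class distance B (mean distance to the
class centroid), between-class distance D (mean over all cross-class
pairs), and their ratio lambda = (B1 + B2)/D — lower lambda means better
separated classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "EvalReport",
    "accuracy",
    "kappa",
    "within_class_distance",
    "between_class_distance",
    "separability_ratio",
]


def _as_labels(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape or pred.ndim != 1 or pred.size == 0:
        raise ValidationError("predicted and actual must be equal-length 1-D, non-empty")
    return pred, act


def accuracy(predicted, actual) -> float:
    """Fraction of correct labels."""
    pred, act = _as_labels(predicted, actual)
    return float(np.mean(pred == act))


def kappa(predicted, actual) -> float:
    """Cohen's kappa ``(po - pe) / (1 - pe)``.

    ``po`` is the observed accuracy; ``pe`` the chance agreement from the
    marginal label distributions of predictions and ground truth.
    """
    pred, act = _as_labels(predicted, actual)
    po = float(np.mean(pred == act))
    classes = np.union1d(pred, act)
    pe = float(
        sum(np.mean(pred == c) * np.mean(act == c) for c in classes)
    )
    if pe >= 1.0:
        raise DegenerateDataError("pe = 1: both marginals are degenerate and equal")
    return (po - pe) / (1.0 - pe)


def _as_points(features) -> np.ndarray:
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValidationError("features must be a non-empty 1-D or 2-D array")
    return x


def within_class_distance(features) -> float:
    """Mean Euclidean distance of class members to the class centroid."""
    x = _as_points(features)
    centroid = x.mean(axis=0)
    return float(np.linalg.norm(x - centroid, axis=1).mean())


def between_class_distance(features1, features2) -> float:
    """Mean Euclidean distance over all cross-class feature pairs."""
    a = _as_points(features1)
    b = _as_points(features2)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("feature dimensionality differs between classes")
    diff = a[:, None, :] - b[None, :, :]
    return float(np.linalg.norm(diff, axis=2).mean())


def separability_ratio(features1, features2) -> float:
    """lambda = (B1 + B2) / D; lower means greater class separability."""
    b1 = within_class_distance(features1)
    b2 = within_class_distance(features2)
    d = between_class_distance(features1, features2)
    if d == 0:
        raise DegenerateDataError("between-class distance D = 0: classes coincide")
    return (b1 + b2) / d


@dataclass(frozen=True)
class EvalReport:
    """Aggregated evaluation of a cross-validated (or held-out) run."""

    accuracy: float
    accuracy_sd: float
    kappa: float
    po: float
    pe: float
    B1: float
    B2: float
    D: float
    lambda_: float
    per_fold: tuple[dict, ...] = ()
    config_digest: str = ""

    @staticmethod
    def from_predictions(
        predicted: Sequence[int],
        actual: Sequence[int],
        features1,
        features2,
        per_fold_accuracies: Sequence[float],
        per_fold: Sequence[dict] = (),
        config: dict | None = None,
    ) -> "EvalReport":
        pred, act = _as_labels(predicted, actual)
        po = accuracy(pred, act)
        classes = np.union1d(pred, act)
        pe = float(sum(np.mean(pred == c) * np.mean(act == c) for c in classes))
        kap = (po - pe) / (1.0 - pe) if pe < 1.0 else float("nan")
        b1 = within_class_distance(features1)
        b2 = within_class_distance(features2)
        d = between_class_distance(features1, features2)
        lam = (b1 + b2) / d if d > 0 else float("inf")
        accs = np.asarray(per_fold_accuracies, dtype=np.float64)
        digest = ""
        if config is not None:
            digest = hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16]
        return EvalReport(
            accuracy=float(accs.mean()),
            accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
            kappa=kap,
            po=po,
            pe=pe,
            B1=b1,
            B2=b2,
            D=d,
            lambda_=lam,
            per_fold=tuple(per_fold),
            config_digest=digest,
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "kappa": self.kappa,
            "po": self.po,
            "pe": self.pe,
            "B1": self.B1,
            "B2": self.B2,
            "D": self.D,
            "lambda": self.lambda_,
            "per_fold": list(self.per_fold),
            "config_digest": self.config_digest,
        }
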