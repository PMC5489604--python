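"""Common spatial pattern algebra.

Given trace-normalized class covariance matrices C1, C2, the composite
C = C1 + C2 is whitened (P C P^T = I), S1 = P C1 P^T is diagonalized by an
orthogonal R (S1 = R D1 R^T), and because S1 + S2 = I the same R
diagonalizes S2 with D2 = I - D1: eigenvalues come in complementary pairs,
so the filter K = R^T P simultaneously maximizes variance for one class
where it minimizes it for the other.  The classification feature is the
normalized variance ratio of the most discriminative filter pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, RankDeficiencyError, ValidationError

__all__ = [
    "CSPModel",
    "class_covariance",
    "whiten",
    "simultaneous_diagonalize",
    "project",
    "feature",
    "feature_vector",
]

_EPS_RANK = 1e-10


@dataclass(frozen=True)
class CSPModel:
    """Whitening P, rotation R, complementary eigenvalues D1/D2, filter K = R^T P."""

    P: np.ndarray
    R: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    K: np.ndarray
    filter_rows_used: tuple[int, int]

    @property
    def p(self) -> int:
        return self.K.shape[0]


def class_covariance(trials: Sequence[np.ndarray]) -> np.ndarray:
    """Mean of per-trial trace-normalized covariances ``(Y Y^T)/trace(Y Y^T)``.

    The result is symmetric PSD with trace 1, making the downstream filter
    invariant to per-trial amplitude scaling.
    """
    trials = [np.atleast_2d(np.asarray(t, dtype=np.float64)) for t in trials]
    if not trials:
        raise ValidationError("need at least one trial")
    p = trials[0].shape[0]
    acc = np.zeros((p, p))
    for k, y in enumerate(trials):
        if y.shape[0] != p:
            raise ValidationError(f"trial {k} has {y.shape[0]} rows, expected {p}")
        cov = y @ y.T
        tr = np.trace(cov)
        if tr <= 0:
            raise DegenerateDataError(f"trial {k} has zero total power (trace 0)")
        acc += cov / tr
    return acc / len(trials)


def whiten(C: np.ndarray) -> np.ndarray:
    """Whitening matrix P with ``P C P^T = I`` from the eigendecomposition of C.

    Eigenvalues are sorted descending; an eigenvalue at or below the rank
    tolerance raises :class:`RankDeficiencyError` (add a ridge ``eps * I``
    to C if regularization is acceptable).
    """
    C = np.asarray(C, dtype=np.float64)
    evals, evecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= _EPS_RANK:
        raise RankDeficiencyError(
            f"covariance eigenvalue {evals[-1]:.3e} <= {_EPS_RANK}; "
            "consider adding a ridge eps*I before whitening"
        )
    return (evecs / np.sqrt(evals)).T


def simultaneous_diagonalize(C1: np.ndarray, C2: np.ndarray) -> CSPModel:
    """Simultaneously diagonalize two class covariances into a CSP filter.

    ``K C1 K^T`` and ``K C2 K^T`` are both diagonal, with complementary
    eigenvalues sorted descending by D1.  Each filter row is signed so its
    largest-magnitude entry is positive.
    """
    C1 = np.asarray(C1, dtype=np.float64)
    C2 = np.asarray(C2, dtype=np.float64)
    if C1.shape != C2.shape or C1.ndim != 2 or C1.shape[0] != C1.shape[1]:
        raise ValidationError("C1 and C2 must be square matrices of equal size")
    P = whiten(C1 + C2)
    S1 = P @ C1 @ P.T
    d1, R = np.linalg.eigh((S1 + S1.T) / 2.0)
    order = np.argsort(d1)[::-1]
    d1, R = d1[order], R[:, order]
    d1 = np.clip(d1, 0.0, 1.0)
    K = R.T @ P
    # fix sign indeterminacy of each eigenvector / filter row
    for i in range(K.shape[0]):
        if K[i, np.argmax(np.abs(K[i]))] < 0:
            K[i] *= -1.0
            R[:, i] *= -1.0
    p = K.shape[0]
    return CSPModel(
        P=P,
        R=R,
        D1=np.diag(d1),
        D2=np.eye(p) - np.diag(d1),
        K=K,
        filter_rows_used=(0, p - 1),
    )


def project(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Spatially filter a trial: ``Z = K @ Y``."""
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    if trial.shape[0] != model.p:
        raise ValidationError(f"trial has {trial.shape[0]} rows, filter expects {model.p}")
    return model.K @ trial


def _row_var(z: np.ndarray, variance: str) -> np.ndarray:
    ddof = 1 if variance == "unbiased" else 0
    return z.var(axis=1, ddof=ddof)


def feature(model: CSPModel, trial: np.ndarray, variance: str = "unbiased") -> float:
    """Scalar variance-ratio feature ``f = var(Z1) / (var(Z1) + var(Z2))``.

    Z1 and Z2 are the projections onto the first and last filter rows (the
    most discriminative filter of each class); f lies in [0, 1] and is
    invariant to scaling the trial by any nonzero constant.
    """
    z = project(model, trial)
    if z.shape[1] < 2:
        raise ValidationError("need at least 2 samples to compute a variance")
    first, last = model.filter_rows_used
    v = _row_var(z[[first, last]], variance)
    denom = v.sum()
    if denom == 0:
        raise DegenerateDataError("var(Z1) + var(Z2) = 0: degenerate trial")
    return float(v[0] / denom)


def feature_vector(
    model: CSPModel, trial: np.ndarray, n_pairs: int = 1, variance: str = "unbiased"
) -> np.ndarray:
    """Normalized variances of the top ``n_pairs`` filter rows of each class.

    For ``n_pairs = 1`` the first entry equals :func:`feature`.
    """
    if not 1 <= n_pairs <= model.p // 2:
        raise ValidationError(f"n_pairs must be in [1, {model.p // 2}]")
    z = project(model, trial)
    rows = list(range(n_pairs)) + list(range(model.p - n_pairs, model.p))
    v = _row_var(z[rows], variance)
    denom = v.sum()
    if denom == 0:
        raise DegenerateDataError("total projected variance is zero")
    return v / denom
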