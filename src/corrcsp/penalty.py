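"""Cross-class temporal-correlation penalty and CCSP filters.

The idea: channels whose time courses look alike across the two classes
carry little discriminative information, so they should contribute less to
the spatial filters.  Channel similarity is measured on the class-average
trials (one ``n x c`` average per class, which keeps the correlation cost
at O(n*c) instead of touching every trial pair): ``R`` holds the Pearson
correlation ``r_ij`` between channel ``i`` of the class-1 average and
channel ``j`` of the class-2 average.  The penalty diagonals are the
row means of |R| (``a_i``, used in the JP1 denominator) and the column
means of |R| (``b_j``, used in the mirrored JP2 denominator).  ``R`` is
generally not symmetric, so the two diagonals differ — the construction is
asymmetric by design.

Plugging ``K1 = diag(a)`` and ``K2 = diag(b)`` into regularized CSP gives
CCSP: as the regularization weight alpha grows, high-correlation channels
acquire larger denominators and hence smaller filter coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .csp import SpatialFilterSet, class_covariance, rcsp_filters, TRACE_NORMALIZED
from .epochs import EpochedSignal

logger = logging.getLogger("corrcsp")

__all__ = [
    "ClassAverage",
    "CorrelationPenalty",
    "class_average",
    "cross_class_correlation",
    "penalty_matrices",
    "ccsp_filters",
]


@dataclass
class ClassAverage:
    """Sample-wise mean trial of one class (``n x c``)."""

    Xbar: np.ndarray
    class_id: int
    n_trials_averaged: int


@dataclass
class CorrelationPenalty:
    """Cross-class channel correlation matrix and its diagonal summaries.

    ``R[i, j]`` is the Pearson correlation between channel ``i`` of the
    first class average and channel ``j`` of the second.  ``a`` holds the
    row means of ``|R|`` and ``b`` the column means; both live in [0, 1].
    """

    R: np.ndarray
    a: np.ndarray
    b: np.ndarray
    class_pair: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "R": self.R.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "class_pair": list(self.class_pair),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationPenalty":
        return cls(
            R=np.asarray(d["R"], dtype=float),
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            class_pair=tuple(d["class_pair"]),
        )


def class_average(signal: EpochedSignal, class_id: int) -> ClassAverage:
    """Element-wise mean of all trials of one class."""
    trials = signal.class_trials(class_id)
    return ClassAverage(
        Xbar=trials.mean(axis=0),
        class_id=int(class_id),
        n_trials_averaged=trials.shape[0],
    )


def cross_class_correlation(
    xbar1: ClassAverage, xbar2: ClassAverage
) -> CorrelationPenalty:
    """Pearson correlations between every channel pair across the two averages.

    Channels with zero variance make the correlation undefined; they
    contribute ``r = 0`` (no similarity evidence) and emit a warning rather
    than propagating NaNs.  The means dividing ``a`` and ``b`` always use
    the full channel count, including zero-filled entries.
    """
    X1, X2 = np.asarray(xbar1.Xbar, float), np.asarray(xbar2.Xbar, float)
    if X1.shape != X2.shape:
        raise ValueError(f"class averages differ in shape: {X1.shape} vs {X2.shape}")
    n, c = X1.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples for correlation; got n={n}")
    Z1 = X1 - X1.mean(axis=0)
    Z2 = X2 - X2.mean(axis=0)
    s1 = np.sqrt((Z1**2).sum(axis=0))
    s2 = np.sqrt((Z2**2).sum(axis=0))
    dead1 = s1 == 0
    dead2 = s2 == 0
    if dead1.any() or dead2.any():
        idx = sorted({int(i) for i in np.where(dead1 | dead2)[0]})
        warnings.warn(
            f"zero-variance channel(s) {idx} in class averages; their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    s1 = np.where(dead1, 1.0, s1)
    s2 = np.where(dead2, 1.0, s2)
    R = (Z1 / s1).T @ (Z2 / s2)
    R[dead1, :] = 0.0
    R[:, dead2] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    absR = np.abs(R)
    return CorrelationPenalty(
        R=R,
        a=absR.mean(axis=1),
        b=absR.mean(axis=0),
        class_pair=(xbar1.class_id, xbar2.class_id),
    )


def penalty_matrices(p: CorrelationPenalty) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal penalty matrices ``K1 = diag(a)`` and ``K2 = diag(b)``."""
    return np.diag(p.a), np.diag(p.b)


def ccsp_filters(
    signal: EpochedSignal,
    class_pair: tuple[int, int],
    alpha: float,
    l: int,
    normalization: str = TRACE_NORMALIZED,
) -> SpatialFilterSet:
    """Correlation-regularized CSP filters for one class pair.

    Composes class covariances, class averages, the cross-class correlation
    penalty and the regularized eigenproblem.  At ``alpha = 0`` the penalty
    vanishes and the result equals standard CSP.
    """
    id1, id2 = class_pair
    C1 = class_covariance(signal, id1, normalization)
    C2 = class_covariance(signal, id2, normalization)
    pen = cross_class_correlation(class_average(signal, id1), class_average(signal, id2))
    K1, K2 = penalty_matrices(pen)
    filters = rcsp_filters(C1, C2, K1, K2, alpha, l, method="ccsp")
    filters.class_pair = (int(id1), int(id2))
    filters.channel_names = signal.channel_names
    return filters
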