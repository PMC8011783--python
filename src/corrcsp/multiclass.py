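"""One-versus-rest extension of CCSP to three or more classes.

For each target class ``g`` the JP1 problem pits the target covariance
against the sum of all other class covariances plus the summed pairwise
correlation penalties,

    JP1: (C_g, sum_{m != g} C_m + alpha * sum_{m != g} diag(a^{g,m})),
    JP2: (sum_{m != g} C_m, C_g + alpha * sum_{m != g} diag(b^{g,m})),

where each pairwise diagonal comes from the cross-class correlation of the
(g, m) class averages.  The pairwise sum is a plain (unnormalized) sum.
One ``2l``-filter bank per class results; at two classes the construction
reduces exactly to the two-class pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .csp import (
    CovarianceEstimate,
    SpatialFilterSet,
    TRACE_NORMALIZED,
    class_covariance,
    solve_rayleigh,
)
from .epochs import EpochedSignal
from .penalty import class_average, cross_class_correlation, penalty_matrices

logger = logging.getLogger("corrcsp")

__all__ = ["OvrFilterBank", "ovr_penalties", "ovr_ccsp_filters", "ovr_decide"]


@dataclass
class OvrFilterBank:
    """One spatial filter set per class, all sharing channel count and ``l``."""

    banks: dict[int, SpatialFilterSet]
    alpha: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.banks:
            raise ValueError("empty filter bank")
        shapes = {fs.W.shape for fs in self.banks.values()}
        if len(shapes) != 1:
            raise ValueError(f"banks disagree on filter shape: {shapes}")
        if not self.alpha:
            self.alpha = {k: fs.alpha for k, fs in self.banks.items()}

    @property
    def n_classes(self) -> int:
        return len(self.banks)

    def to_dict(self) -> dict:
        return {
            "banks": {str(k): fs.to_dict() for k, fs in self.banks.items()},
            "alpha": {str(k): v for k, v in self.alpha.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OvrFilterBank":
        return cls(
            banks={int(k): SpatialFilterSet.from_dict(v) for k, v in d["banks"].items()},
            alpha={int(k): float(v) for k, v in d.get("alpha", {}).items()},
        )


def ovr_penalties(
    signal: EpochedSignal, target_class: int
) -> tuple[np.ndarray, np.ndarray]:
    """Summed pairwise correlation penalties of the target against each other class.

    ``K1`` sums the ``diag(a)`` of every (target, other) pair; ``K2`` sums
    the ``diag(b)``.  With fewer than two non-target classes the problem is
    the two-class one and callers should use the pairwise path directly.
    """
    others = [c for c in signal.classes if c != target_class]
    if target_class not in signal.classes:
        raise ValueError(f"class {target_class} absent from signal")
    if len(others) < 2:
        raise ValueError(
            "one-versus-rest penalties need at least 2 non-target classes; "
            "use the two-class correlation penalty instead"
        )
    xbar_t = class_average(signal, target_class)
    c = signal.n_channels
    K1 = np.zeros((c, c))
    K2 = np.zeros((c, c))
    for m in others:
        pen = cross_class_correlation(xbar_t, class_average(signal, m))
        k1, k2 = penalty_matrices(pen)
        K1 += k1
        K2 += k2
    return K1, K2


def ovr_ccsp_filters(
    signal: EpochedSignal,
    target_class: int,
    alpha: float,
    l: int,
    normalization: str = TRACE_NORMALIZED,
) -> SpatialFilterSet:
    """CCSP filter set discriminating one class against the pooled rest."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0; got {alpha}")
    classes = list(signal.classes)
    if target_class not in classes:
        raise ValueError(f"class {target_class} absent from signal")
    others = [m for m in classes if m != target_class]
    if not others:
        raise ValueError("need at least two classes")
    Ct = class_covariance(signal, target_class, normalization).C
    Crest = sum(class_covariance(signal, m, normalization).C for m in others)
    if len(others) == 1:
        # two-class reduction: the pairwise penalty
        pen = cross_class_correlation(
            class_average(signal, target_class), class_average(signal, others[0])
        )
        K1, K2 = penalty_matrices(pen)
    else:
        K1, K2 = ovr_penalties(signal, target_class)
    c = signal.n_channels
    if not (1 <= l <= c // 2):
        raise ValueError(f"need 1 <= l <= c//2 = {c // 2}; got l={l}")
    v1, W1 = solve_rayleigh(Ct, Crest + alpha * K1)
    v2, W2 = solve_rayleigh(Crest, Ct + alpha * K2)
    return SpatialFilterSet(
        W=np.vstack([W1[:l], W2[:l]]),
        eigenvalues=np.concatenate([v1[:l], v2[:l]]),
        l=l,
        method="ccsp",
        alpha=float(alpha),
        class_pair=(int(target_class), -1),  # -1 marks "rest"
        channel_names=signal.channel_names,
    )


def ovr_decide(scores: dict[int, float] | np.ndarray) -> int:
    """Argmax over per-class scores; ties go to the lowest class id (logged).

    ``scores`` maps class id to a finite real score, or is an array whose
    index ``i`` scores class ``i + 1``.
    """
    if isinstance(scores, dict):
        ids = sorted(scores)
        vals = np.array([scores[i] for i in ids], dtype=float)
    else:
        vals = np.asarray(scores, dtype=float)
        ids = list(range(1, vals.size + 1))
    if vals.size == 0:
        raise ValueError("no scores given")
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite score in {vals.tolist()}")
    best = np.flatnonzero(vals == vals.max())
    if best.size > 1:
        logger.warning(
            "tied one-versus-rest scores for classes %s; choosing %s",
            [ids[i] for i in best],
            ids[best[0]],
        )
    return ids[best[0]]
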