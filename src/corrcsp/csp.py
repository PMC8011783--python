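"""Covariance estimation and (regularized) common spatial pattern filters.

CSP finds spatial filters ``w`` maximizing the Rayleigh quotient

    J(w) = w' C1 w / w' C2 w,

where ``C1``/``C2`` are class spatial covariances.  Its regularized form
adds a quadratic penalty to the denominator,

    J_P1(w) = w' C1 w / (w' (C2 + alpha K) w),

with ``K`` encoding prior information (``K = I`` is Tikhonov-regularized
CSP; the correlation penalty of :mod:`corrcsp.penalty` is the diagonal of
cross-class channel correlations).  Both are solved as symmetric-definite
generalized eigenproblems; the top-``l`` eigenvectors of the (C1, C2+aK)
problem and of the mirrored (C2, C1+aK) problem together form the ``2l``
filters.  Each filter is scaled to the Lagrangian constraint
``w' C_den w = 1`` and sign-canonicalized (largest-magnitude coefficient
positive) so results are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .epochs import EpochedSignal

logger = logging.getLogger("corrcsp")

__all__ = [
    "CovarianceEstimate",
    "SpatialFilterSet",
    "trial_covariance",
    "class_covariance",
    "solve_rayleigh",
    "csp_filters",
    "rcsp_filters",
]

#: default covariance normalization policy
TRACE_NORMALIZED = "trace_normalized_mean"
RAW_SUM = "raw_sum"
_POLICIES = (TRACE_NORMALIZED, RAW_SUM)

#: relative ridge added to a denominator matrix that is not positive definite
RIDGE_EPS = 1e-10


@dataclass
class CovarianceEstimate:
    """Per-class spatial covariance with its normalization policy recorded."""

    C: np.ndarray
    class_id: int
    normalization: str
    n_trials: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        c = self.C.shape[0]
        if self.C.shape != (c, c):
            raise ValueError(f"covariance must be square; got {self.C.shape}")
        sym_err = np.abs(self.C - self.C.T).max()
        scale = max(np.abs(self.C).max(), 1.0)
        if sym_err > 1e-10 * scale:
            raise ValueError(f"covariance not symmetric (max asymmetry {sym_err:g})")
        if self.normalization not in _POLICIES:
            raise ValueError(f"unknown normalization policy {self.normalization!r}")


@dataclass
class SpatialFilterSet:
    """``2l`` spatial filters: rows 1..l from the JP1 problem, l+1..2l from JP2.

    ``W`` holds the filters as rows.  ``eigenvalues[i]`` is the generalized
    eigenvalue of filter ``i`` in its own problem, and ``side_of_origin``
    tags each row with the problem it solves.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    l: int
    method: str
    alpha: float
    side_of_origin: list[str] = field(default_factory=list)
    class_pair: tuple[int, int] | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.W.shape[0] != 2 * self.l:
            raise ValueError(f"expected {2 * self.l} filters, got {self.W.shape[0]}")
        if self.eigenvalues.shape != (2 * self.l,):
            raise ValueError("one eigenvalue per filter required")
        if not self.side_of_origin:
            self.side_of_origin = ["jp1"] * self.l + ["jp2"] * self.l

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "l": self.l,
            "method": self.method,
            "alpha": self.alpha,
            "side_of_origin": self.side_of_origin,
            "class_pair": list(self.class_pair) if self.class_pair else None,
            "channel_names": self.channel_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialFilterSet":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            l=int(d["l"]),
            method=d["method"],
            alpha=float(d["alpha"]),
            side_of_origin=list(d.get("side_of_origin") or []),
            class_pair=tuple(d["class_pair"]) if d.get("class_pair") else None,
            channel_names=d.get("channel_names"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SpatialFilterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- covariance estimation ---------------------------------------------------

def trial_covariance(trial: np.ndarray, normalization: str = TRACE_NORMALIZED) -> np.ndarray:
    """Spatial covariance ``X' X`` of a single ``n x c`` trial.

    Under ``trace_normalized_mean`` the matrix is divided by its trace, so
    every trial contributes on the same scale regardless of amplitude.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"trial must be n x c with n >= 2; got shape {X.shape}")
    if normalization not in _POLICIES:
        raise ValueError(f"unknown normalization policy {normalization!r}")
    C = X.T @ X
    if normalization == TRACE_NORMALIZED:
        tr = np.trace(C)
        if tr <= 0:
            raise ValueError("all-zero trial: trace normalization undefined")
        C = C / tr
    return 0.5 * (C + C.T)  # symmetry is exact in arithmetic; enforce in floats


def class_covariance(
    signal: EpochedSignal, class_id: int, normalization: str = TRACE_NORMALIZED
) -> CovarianceEstimate:
    """Mean of per-trial covariances over one class."""
    trials = signal.class_trials(class_id)
    covs = np.empty((trials.shape[0], signal.n_channels, signal.n_channels))
    for i, trial in enumerate(trials):
        try:
            covs[i] = trial_covariance(trial, normalization)
        except ValueError as exc:
            raise ValueError(f"class {class_id}, trial {i}: {exc}") from exc
    return CovarianceEstimate(
        C=covs.mean(axis=0),
        class_id=int(class_id),
        normalization=normalization,
        n_trials=trials.shape[0],
    )


# -- generalized eigenproblem ------------------------------------------------

def _canonical_sign(W: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude coefficient is positive."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def solve_rayleigh(Cnum: np.ndarray, Cden: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All generalized eigenpairs of ``Cnum w = lambda Cden w``.

    Returns eigenvalues sorted descending and the matching eigenvectors as
    rows, each scaled so ``w' Cden w = 1`` and sign-canonicalized.  The top
    eigenvector maximizes the Rayleigh quotient ``w'Cnum w / w'Cden w``.

    ``Cden`` must be positive definite; if it is not, a small ridge
    ``RIDGE_EPS * trace(Cden)/c * I`` is added once (and logged) before
    giving up.
    """
    A = np.asarray(Cnum, dtype=float)
    B = np.asarray(Cden, dtype=float)
    c = A.shape[0]
    if A.shape != (c, c) or B.shape != (c, c):
        raise ValueError(f"need two square matrices of equal size; got {A.shape}, {B.shape}")
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)

    def _try(Bmat: np.ndarray):
        try:
            vals, vecs = linalg.eigh(A, Bmat)
        except (linalg.LinAlgError, ValueError):
            return None
        if not (np.isfinite(vals).all() and np.isfinite(vecs).all()):
            return None
        return vals, vecs

    out = _try(B)
    if out is None:
        ridge = RIDGE_EPS * max(np.trace(B), 1e-300) / c
        logger.warning("denominator matrix not positive definite; adding ridge %g", ridge)
        out = _try(B + ridge * np.eye(c))
        if out is None:
            cond = np.linalg.cond(B)
            raise ValueError(
                f"denominator matrix singular beyond ridge repair "
                f"(condition number {cond:.3g})"
            )
    vals, vecs = out
    order = np.argsort(vals, kind="stable")[::-1]
    vals = vals[order]
    W = vecs[:, order].T  # scipy returns v with v' B v = I already
    # ties: stable sort above, then order by first differing coefficient
    for lo in range(len(vals) - 1):
        if np.isclose(vals[lo], vals[lo + 1], rtol=1e-12, atol=0):
            hi = lo + 1
            while hi + 1 < len(vals) and np.isclose(vals[lo], vals[hi + 1], rtol=1e-12, atol=0):
                hi += 1
            block = _canonical_sign(W[lo : hi + 1])
            key = np.lexsort(block.T[::-1])
            W[lo : hi + 1] = block[key]
    W = _canonical_sign(W)
    # residual check per pair
    res = np.abs(A @ W.T - B @ W.T * vals[None, :]).max(axis=0)
    tol = 1e-8 * max(np.abs(A).max(), 1.0)
    bad = res > tol
    if bad.any():
        logger.warning("eigenpair residual up to %g exceeds %g", res.max(), tol)
    return vals, W


def _top_l(Cnum: np.ndarray, Cden: np.ndarray, l: int) -> tuple[np.ndarray, np.ndarray]:
    vals, W = solve_rayleigh(Cnum, Cden)
    return vals[:l], W[:l]


def csp_filters(
    C1: CovarianceEstimate, C2: CovarianceEstimate, l: int
) -> SpatialFilterSet:
    """Standard CSP: top-``l`` eigenvectors of (C1, C2) and of (C2, C1).

    The (C2, C1) problem's top eigenvectors span the same directions as the
    lowest eigenvectors of (C1, C2); solving both sides keeps the scaling
    convention symmetric.
    """
    return rcsp_filters(C1, C2, K1=None, K2=None, alpha=0.0, l=l, method="csp")


def rcsp_filters(
    C1: CovarianceEstimate,
    C2: CovarianceEstimate,
    K1: np.ndarray | None,
    K2: np.ndarray | None,
    alpha: float,
    l: int,
    method: str = "trcsp",
) -> SpatialFilterSet:
    """Regularized CSP filters with quadratic penalties ``K1`` (JP1) / ``K2`` (JP2).

    JP1 solves ``(C1, C2 + alpha K1)``, JP2 solves ``(C2, C1 + alpha K2)``.
    ``K=None`` means the identity (Tikhonov) penalty.
    """
    if alpha < 0:
        raise ValueError(f"regularization weight alpha must be >= 0; got {alpha}")
    c = C1.C.shape[0]
    if C2.C.shape[0] != c:
        raise ValueError("class covariances have mismatched channel counts")
    if not (1 <= l <= c // 2):
        raise ValueError(f"need 1 <= l <= c//2 = {c // 2}; got l={l}")
    K1 = np.eye(c) if K1 is None else np.asarray(K1, dtype=float)
    K2 = np.eye(c) if K2 is None else np.asarray(K2, dtype=float)
    for name, K in (("K1", K1), ("K2", K2)):
        if K.shape != (c, c):
            raise ValueError(f"{name} must be {c} x {c}; got {K.shape}")
        if np.abs(K - K.T).max() > 1e-10 * max(np.abs(K).max(), 1.0):
            raise ValueError(f"{name} must be symmetric")
    v1, W1 = _top_l(C1.C, C2.C + alpha * K1, l)
    v2, W2 = _top_l(C2.C, C1.C + alpha * K2, l)
    return SpatialFilterSet(
        W=np.vstack([W1, W2]),
        eigenvalues=np.concatenate([v1, v2]),
        l=l,
        method=method,
        alpha=float(alpha),
        class_pair=(C1.class_id, C2.class_id),
    )
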