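"""Synthetic motor-imagery-like EEG with known ground truth.

Trials are generated by the linear mixing model the CSP family assumes:
``X = S A' + noise`` with a fixed ``c x s`` mixing matrix ``A`` and
band-limited (8-30 Hz) Gaussian sources whose variance depends on class.

Three source roles:

* *discriminative* — variance ``v_high`` in one class, ``v_low`` in the
  others (two-class data gets a mirrored pair; multi-class one per class).
  Variance, not waveform, is the only class signal, which is exactly the
  statistic CSP detects.
* *shared background* — identical in distribution across classes.  Each
  has a fixed waveform drawn once per dataset, present in every trial with
  variance share ``shared_corr`` (the rest of its power is fresh noise per
  trial).  The common waveform survives class averaging, which is what
  drives the cross-class correlation the CCSP penalty measures:
  ``shared_corr = 0`` gives uncorrelated class averages, ``shared_corr``
  near 1 strongly correlated ones.
* sensor noise — spatially white broadband Gaussian; ``snr_db`` is the
  per-channel average power ratio of the mixed sources to this noise.

The ground truth records the mixing matrix, source roles and class
variances; ``unmixing`` (the pseudo-inverse of ``A``) gives the ideal
spatial filters against which recovery is measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .epochs import EpochedSignal

__all__ = ["SyntheticGroundTruth", "generate_two_class", "generate_multiclass"]


@dataclass
class SyntheticGroundTruth:
    """Everything needed to check recovery against the generating model."""

    A: np.ndarray                      # c x s mixing matrix
    source_roles: list[str]            # per-source: discriminative | shared_background
    class_variances: np.ndarray        # n_classes x s source variances
    snr_db: float
    shared_corr: float
    seed: int
    discriminative_for: list[int | None] = field(default_factory=list)

    @property
    def unmixing(self) -> np.ndarray:
        """Pseudo-inverse of the mixing matrix; row i unmixes source i."""
        return np.linalg.pinv(self.A)

    def discriminative_index(self, class_id: int) -> int:
        """Index of the source whose variance is boosted in ``class_id``."""
        for i, g in enumerate(self.discriminative_for):
            if g == class_id:
                return i
        raise ValueError(f"no discriminative source for class {class_id}")

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "source_roles": self.source_roles,
            "class_variances": self.class_variances.tolist(),
            "snr_db": self.snr_db,
            "shared_corr": self.shared_corr,
            "seed": self.seed,
            "discriminative_for": self.discriminative_for,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to 8-30 Hz along the last axis."""
    sos = sps.butter(5, [8.0, 30.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _generate(
    n_classes: int,
    c: int,
    n: int,
    trials_per_class: int,
    snr_db: float,
    shared_corr: float,
    fs: float,
    seed: int,
    n_background: int,
    v_high: float,
    v_low: float,
) -> tuple[EpochedSignal, SyntheticGroundTruth]:
    if c < 3:
        raise ValueError(f"need at least 3 channels; got {c}")
    if not (0.0 <= shared_corr <= 1.0):
        raise ValueError(f"shared_corr must lie in [0, 1]; got {shared_corr}")
    if n < 64:
        raise ValueError(f"need at least 64 samples per trial; got {n}")
    if trials_per_class < 1:
        raise ValueError("need at least one trial per class")
    if not np.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite; got {snr_db}")
    n_disc = 2 if n_classes == 2 else n_classes
    s = n_disc + n_background
    if s > c:
        raise ValueError(
            f"{s} sources exceed {c} channels; full column rank impossible"
        )
    rng = np.random.default_rng(seed)

    # random orthonormal-column mixing: full column rank by construction and a
    # well-conditioned ideal unmixing (pinv(A) = A'), so filter-recovery
    # checks measure the estimator, not the conditioning of the head model
    A = np.linalg.qr(rng.standard_normal((c, s)))[0]

    roles = ["discriminative"] * n_disc + ["shared_background"] * n_background
    if n_classes == 2:
        disc_for: list[int | None] = [1, 2]
    else:
        disc_for = list(range(1, n_classes + 1))
    disc_for += [None] * n_background

    # class-conditional source variances
    var = np.full((n_classes, s), 1.0)
    for i in range(n_disc):
        var[:, i] = v_low
        var[disc_for[i] - 1, i] = v_high

    # fixed shared-background waveforms (drawn once per dataset)
    common = _band_limited_noise(rng, (n_background, n), fs) if n_background else None

    n_trials = n_classes * trials_per_class
    labels = np.repeat(np.arange(1, n_classes + 1), trials_per_class)
    order = rng.permutation(n_trials)  # interleave classes
    labels = labels[order]

    data = np.empty((n_trials, n, c))
    for t in range(n_trials):
        g = labels[t] - 1
        S = np.empty((s, n))
        fresh = _band_limited_noise(rng, (s, n), fs)
        for i in range(s):
            sd = np.sqrt(var[g, i])
            if roles[i] == "shared_background" and n_background:
                j = i - n_disc
                S[i] = sd * (
                    np.sqrt(shared_corr) * common[j]
                    + np.sqrt(1.0 - shared_corr) * fresh[i]
                )
            else:
                S[i] = sd * fresh[i]
        data[t] = S.T @ A.T

    # white sensor noise scaled to the requested per-channel average SNR
    sig_power = np.mean(data**2)
    noise_power = sig_power / (10.0 ** (snr_db / 10.0))
    data += np.sqrt(noise_power) * rng.standard_normal(data.shape)

    signal = EpochedSignal(data=data, labels=labels, fs=fs)
    truth = SyntheticGroundTruth(
        A=A,
        source_roles=roles,
        class_variances=var,
        snr_db=float(snr_db),
        shared_corr=float(shared_corr),
        seed=int(seed),
        discriminative_for=disc_for,
    )
    return signal, truth


def generate_two_class(
    c: int = 8,
    n: int = 500,
    trials_per_class: int = 100,
    snr_db: float = 10.0,
    shared_corr: float = 0.5,
    fs: float = 250.0,
    seed: int = 0,
    n_background: int = 4,
    v_high: float = 4.0,
    v_low: float = 1.0,
) -> tuple[EpochedSignal, SyntheticGroundTruth]:
    """Two-class dataset: a mirrored pair of discriminative sources.

    Source 0 has variance ``v_high`` in class 1 and ``v_low`` in class 2;
    source 1 mirrors this.  Defaults give 8 channels, 2-second trials at
    250 Hz, 100 trials per class at 10 dB SNR with half of the background
    power shared across classes.
    """
    return _generate(
        2, c, n, trials_per_class, snr_db, shared_corr, fs, seed,
        n_background, v_high, v_low,
    )


def generate_multiclass(
    n_classes: int = 4,
    c: int = 10,
    n: int = 500,
    trials_per_class: int = 100,
    snr_db: float = 10.0,
    shared_corr: float = 0.5,
    fs: float = 250.0,
    seed: int = 0,
    n_background: int = 4,
    v_high: float = 4.0,
    v_low: float = 1.0,
) -> tuple[EpochedSignal, SyntheticGroundTruth]:
    """Multi-class dataset: one discriminative source per class."""
    if n_classes not in (3, 4):
        raise ValueError(f"n_classes must be 3 or 4; got {n_classes}")
    return _generate(
        n_classes, c, n, trials_per_class, snr_db, shared_corr, fs, seed,
        n_background, v_high, v_low,
    )
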