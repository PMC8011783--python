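"""Shared fixtures: small deterministic signals and cached synthetic datasets."""

import numpy as np
import pytest

from corrcsp import EpochedSignal, generate_multiclass, generate_two_class


def split_even_odd(signal: EpochedSignal):
    """Deterministic half/half split of one dataset (same generating system)."""
    idx = np.arange(signal.n_trials)
    return signal.subset(idx % 2 == 0), signal.subset(idx % 2 == 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_class_dataset():
    """Default-condition two-class data: 200 trials/class, split in half."""
    signal, truth = generate_two_class(trials_per_class=200, seed=101)
    train, test = split_even_odd(signal)
    return train, test, truth


@pytest.fixture(scope="session")
def four_class_dataset():
    signal, truth = generate_multiclass(n_classes=4, trials_per_class=100, seed=303)
    train, test = split_even_odd(signal)
    return train, test, truth


@pytest.fixture(scope="session")
def small_two_class():
    """Cheap two-class set for plumbing tests (30 trials/class, short trials)."""
    signal, truth = generate_two_class(
        c=6, n=256, trials_per_class=30, n_background=3, seed=5
    )
    return signal, truth


def random_spd(rng: np.random.Generator, c: int) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    B = rng.standard_normal((c, c))
    return B @ B.T + c * np.eye(c) * 0.1


def make_signal(trials_by_class: dict[int, list[np.ndarray]], fs: float = 100.0):
    """EpochedSignal from explicit per-class trial lists."""
    data, labels = [], []
    for cid in sorted(trials_by_class):
        for t in trials_by_class[cid]:
            data.append(np.asarray(t, dtype=float))
            labels.append(cid)
    return EpochedSignal(data=np.array(data), labels=np.array(labels), fs=fs)
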