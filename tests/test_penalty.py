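"""Cross-class correlation penalty: class averages, R, diagonals, CCSP filters."""

import numpy as np
import pytest

from corrcsp import (
    ClassAverage,
    ccsp_filters,
    class_average,
    class_covariance,
    cross_class_correlation,
    csp_filters,
    generate_two_class,
    penalty_matrices,
    rcsp_filters,
    solve_rayleigh,
)
from conftest import make_signal


def pearson_oracle(x, y):
    """Brute-force Pearson correlation straight from the defining formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def avg(mat, class_id=1, t=1):
    return ClassAverage(Xbar=np.asarray(mat, float), class_id=class_id,
                        n_trials_averaged=t)


# -- class averages ----------------------------------------------------------

def test_class_average_examples():
    A = np.array([[0.0, 0.0], [1.0, 2.0]])
    sig = make_signal({1: [A, A], 2: [np.zeros((2, 2)), np.array([[2, 4], [0, 0.0]])]})
    np.testing.assert_array_equal(class_average(sig, 1).Xbar, A)
    np.testing.assert_array_equal(class_average(sig, 2).Xbar, [[1, 2], [0, 0]])
    assert class_average(sig, 1).n_trials_averaged == 2


def test_average_of_noise_shrinks_like_sqrt_t(rng):
    n, c = 200, 4
    for t, tol in [(4, 0.35), (64, 0.3)]:
        trials = rng.standard_normal((t, n, c))
        sig = make_signal({1: list(trials), 2: [np.ones((n, c))]})
        rms = class_average(sig, 1).Xbar.std()
        assert rms == pytest.approx(1.0 / np.sqrt(t), rel=tol)


# -- cross-class correlation -------------------------------------------------

def test_worked_correlation_example_matches_hand_computation():
    """Two 3-sample channels per class; all four Pearson pairs done by hand."""
    X1 = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
    X2 = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]])
    p = cross_class_correlation(avg(X1, 1), avg(X2, 2))
    np.testing.assert_allclose(p.R, [[1.0, 0.5], [-1.0, -0.5]], atol=1e-12)
    np.testing.assert_allclose(p.a, [0.75, 0.75], atol=1e-12)
    np.testing.assert_allclose(p.b, [1.0, 0.5], atol=1e-12)
    # independent oracle over every channel pair
    for i in range(2):
        for j in range(2):
            assert p.R[i, j] == pytest.approx(pearson_oracle(X1[:, i], X2[:, j]))
    K1, K2 = penalty_matrices(p)
    np.testing.assert_allclose(K1, np.diag([0.75, 0.75]))
    np.testing.assert_allclose(K2, np.diag([1.0, 0.5]))


def test_self_correlation_of_orthogonal_channels_is_identity(rng):
    q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
    q -= q.mean(axis=0)  # zero-mean, (near-)orthogonal columns
    q, _ = np.linalg.qr(q)
    p = cross_class_correlation(avg(q, 1), avg(q, 2))
    np.testing.assert_allclose(p.R, np.eye(3), atol=1e-8)


def test_negating_one_class_flips_r_but_not_penalties(rng):
    X = rng.standard_normal((30, 4))
    p_pos = cross_class_correlation(avg(X, 1), avg(X + rng.standard_normal(X.shape), 2))
    p_neg = cross_class_correlation(
        avg(X, 1), avg(-(X + 0), 2)
    )
    p_ref = cross_class_correlation(avg(X, 1), avg(X, 2))
    np.testing.assert_allclose(p_neg.R, -p_ref.R, atol=1e-12)
    np.testing.assert_allclose(p_neg.a, p_ref.a, atol=1e-12)
    np.testing.assert_allclose(p_neg.b, p_ref.b, atol=1e-12)
    assert np.all(np.abs(p_pos.R) <= 1.0)
    assert np.all((p_pos.a >= 0) & (p_pos.a <= 1))


def test_zero_variance_channel_warns_and_zeroes(rng):
    X1 = rng.standard_normal((10, 3))
    X1[:, 1] = 5.0  # flat channel
    X2 = rng.standard_normal((10, 3))
    with pytest.warns(RuntimeWarning, match=r"zero-variance channel\(s\) \[1\]"):
        p = cross_class_correlation(avg(X1, 1), avg(X2, 2))
    np.testing.assert_array_equal(p.R[1, :], 0.0)
    assert np.isfinite(p.R).all()
    # means still divide by the full channel count
    assert p.a[1] == 0.0


def test_shape_and_length_rejections(rng):
    with pytest.raises(ValueError, match="shape"):
        cross_class_correlation(avg(np.zeros((5, 2))), avg(np.zeros((5, 3)), 2))
    with pytest.raises(ValueError, match="2 samples"):
        cross_class_correlation(avg(np.zeros((1, 2))), avg(np.zeros((1, 2)), 2))


# -- CCSP filters ------------------------------------------------------------

def test_ccsp_alpha_zero_equals_csp(small_two_class):
    sig, _ = small_two_class
    a = ccsp_filters(sig, (1, 2), alpha=0.0, l=2)
    b = csp_filters(class_covariance(sig, 1), class_covariance(sig, 2), l=2)
    np.testing.assert_array_equal(a.W, b.W)
    assert a.method == "ccsp"


def test_extreme_penalties_reduce_to_csp_and_trcsp(rng):
    """R == 0 leaves CSP untouched at any alpha; |R| == 1 coincides with TRCSP."""
    n = 40
    sig = make_signal({1: [rng.standard_normal((n, 4))], 2: [rng.standard_normal((n, 4))]})
    C1 = class_covariance(sig, 1)
    C2 = class_covariance(sig, 2)
    zeros = np.zeros((4, 4))
    eye = np.eye(4)
    for alpha in [0.0, 0.3, 2.0]:
        z = rcsp_filters(C1, C2, zeros, zeros, alpha, l=2, method="ccsp")
        c = csp_filters(C1, C2, l=2)
        np.testing.assert_allclose(z.W, c.W, atol=1e-10)
        o = rcsp_filters(C1, C2, eye, eye, alpha, l=2, method="ccsp")
        t = rcsp_filters(C1, C2, None, None, alpha, l=2)
        np.testing.assert_allclose(o.W, t.W, atol=1e-10)


def test_ccsp_recovers_ground_truth_direction():
    sig, truth = generate_two_class(seed=42)
    u = truth.unmixing[truth.discriminative_index(1)]
    w = ccsp_filters(sig, (1, 2), alpha=1e-4, l=3).W[0]
    cos = abs(w @ u) / (np.linalg.norm(w) * np.linalg.norm(u))
    assert cos >= np.cos(np.deg2rad(18.0))


def test_channel_permutation_equivariance(small_two_class):
    sig, _ = small_two_class
    perm = np.array([3, 0, 4, 1, 5, 2])
    permuted = sig.subset(np.arange(sig.n_trials))
    permuted.data = sig.data[:, :, perm]
    a = ccsp_filters(sig, (1, 2), alpha=1e-3, l=2)
    b = ccsp_filters(permuted, (1, 2), alpha=1e-3, l=2)
    np.testing.assert_allclose(b.W, a.W[:, perm], atol=1e-8)


def test_jp1_eigenvalues_non_increasing_in_alpha(small_two_class):
    sig, _ = small_two_class
    prev = None
    for alpha in np.linspace(0.0, 0.02, 6):
        ev = ccsp_filters(sig, (1, 2), alpha=float(alpha), l=2).eigenvalues[:2]
        if prev is not None:
            assert np.all(ev <= prev + 1e-12)
        prev = ev


def test_higher_correlation_channel_loses_weight():
    """Two covariance-exchangeable channels; the one with the larger penalty
    entry must get a monotonically smaller squared filter coefficient."""
    C1 = np.array([[4.0, 1.8, 0.0], [1.8, 4.0, 0.0], [0.0, 0.0, 1.0]])
    C2 = np.eye(3)
    K1 = np.diag([0.8, 0.2, 0.5])  # channel 0 is the high-correlation one
    prev = None
    for alpha in np.linspace(0.0, 2.0, 10):
        _, W = solve_rayleigh(C1, C2 + alpha * K1)
        w = W[0] / np.linalg.norm(W[0])
        if prev is not None:
            assert w[0] ** 2 <= prev + 1e-12
        prev = w[0] ** 2
    assert prev < 0.2  # started at 0.5


def test_penalty_serialization_roundtrip(rng):
    from corrcsp import CorrelationPenalty

    p = cross_class_correlation(
        avg(rng.standard_normal((20, 3)), 1), avg(rng.standard_normal((20, 3)), 2)
    )
    back = CorrelationPenalty.from_dict(p.to_dict())
    np.testing.assert_array_equal(back.R, p.R)
    assert back.class_pair == p.class_pair
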