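"""Covariance estimation and the generalized-eigenvalue spatial filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrcsp import (
    CovarianceEstimate,
    class_covariance,
    csp_filters,
    rcsp_filters,
    solve_rayleigh,
    trial_covariance,
)
from conftest import make_signal, random_spd


def cov_est(C, class_id=1):
    return CovarianceEstimate(C=np.asarray(C, float), class_id=class_id,
                              normalization="raw_sum", n_trials=1)


# -- trial / class covariance ------------------------------------------------

@pytest.mark.parametrize(
    "X,policy,expected",
    [
        ([[1, 0], [0, 1]], "raw_sum", [[1, 0], [0, 1]]),
        ([[1, 0], [0, 1]], "trace_normalized_mean", [[0.5, 0], [0, 0.5]]),
        ([[1, 2], [3, 4]], "raw_sum", [[10, 14], [14, 20]]),
    ],
)
def test_trial_covariance_examples(X, policy, expected):
    np.testing.assert_allclose(trial_covariance(np.array(X, float), policy), expected)


def test_trial_covariance_rejects_degenerate():
    with pytest.raises(ValueError, match="all-zero"):
        trial_covariance(np.zeros((5, 3)), "trace_normalized_mean")
    with pytest.raises(ValueError, match="n >= 2"):
        trial_covariance(np.ones((1, 3)))
    with pytest.raises(ValueError, match="policy"):
        trial_covariance(np.ones((3, 3)), "bogus")


def test_class_covariance_mean_and_normalization():
    I2 = np.eye(2)
    sig = make_signal({1: [I2, 2 * I2], 2: [I2]})
    est = class_covariance(sig, 1, "trace_normalized_mean")
    np.testing.assert_allclose(est.C, np.diag([0.5, 0.5]))  # both normalize alike
    assert est.n_trials == 2 and est.class_id == 1
    single = class_covariance(sig, 2, "raw_sum")
    np.testing.assert_allclose(single.C, I2)  # one trial -> its own covariance
    with pytest.raises(ValueError, match="class id 7"):
        class_covariance(sig, 7)


# -- generalized eigenproblem ------------------------------------------------

def test_solve_rayleigh_diagonal_case():
    vals, W = solve_rayleigh(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]))
    np.testing.assert_allclose(vals, [4.0, 0.25], atol=1e-12)
    np.testing.assert_allclose(np.abs(W), [[1, 0], [0, 0.5]], atol=1e-12)


def test_solve_rayleigh_identity():
    vals, _ = solve_rayleigh(np.eye(3), np.eye(3))
    np.testing.assert_allclose(vals, 1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_top_eigenvector_beats_random_filters(seed):
    """Brute-force Rayleigh-quotient oracle: no sampled direction scores higher."""
    rng = np.random.default_rng(seed)
    Cn, Cd = random_spd(rng, 3), random_spd(rng, 3)
    vals, W = solve_rayleigh(Cn, Cd)
    V = rng.standard_normal((2000, 3))
    quotients = np.einsum("ij,jk,ik->i", V, Cn, V) / np.einsum(
        "ij,jk,ik->i", V, Cd, V
    )
    assert vals[0] >= quotients.max() - 1e-9
    w = W[0]
    assert w @ Cn @ w / (w @ Cd @ w) == pytest.approx(vals[0])


def test_solver_postconditions(rng):
    """Constraint scaling, residuals and canonical signs on a random instance."""
    Cn, Cd = random_spd(rng, 5), random_spd(rng, 5)
    vals, W = solve_rayleigh(Cn, Cd)
    assert np.all(np.diff(vals) <= 1e-12)  # descending
    for lam, w in zip(vals, W):
        assert w @ Cd @ w == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(Cn @ w - lam * Cd @ w) <= 1e-8 * np.linalg.norm(Cn)
        assert w[np.argmax(np.abs(w))] > 0  # sign canonicalization


def test_singular_denominator_rejected():
    with pytest.raises(ValueError, match="condition"):
        solve_rayleigh(np.eye(2), np.zeros((2, 2)))


# -- CSP / RCSP filter sets --------------------------------------------------

def test_csp_diagonal_case_axes_and_mirroring():
    fs = csp_filters(cov_est(np.diag([4.0, 1.0]), 1), cov_est(np.diag([1.0, 4.0]), 2), l=1)
    np.testing.assert_allclose(np.abs(fs.W) > 1e-12, [[True, False], [False, True]])
    np.testing.assert_allclose(fs.eigenvalues, [4.0, 4.0])  # each problem's own top
    assert fs.side_of_origin == ["jp1", "jp2"]
    assert fs.method == "csp" and fs.alpha == 0.0


def test_indistinguishable_classes_give_unit_eigenvalues(rng):
    C = random_spd(rng, 4)
    fs = csp_filters(cov_est(C, 1), cov_est(C, 2), l=2)
    np.testing.assert_allclose(fs.eigenvalues, 1.0, atol=1e-10)


def test_csp_row_one_is_monte_carlo_optimal(rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    fs = csp_filters(cov_est(C1, 1), cov_est(C2, 2), l=2)
    w = fs.W[0]
    best = w @ C1 @ w / (w @ C2 @ w)
    V = rng.standard_normal((10_000, 4))
    ratios = np.einsum("ij,jk,ik->i", V, C1, V) / np.einsum("ij,jk,ik->i", V, C2, V)
    assert best >= ratios.max() - 1e-9


def test_l_out_of_range_rejected(rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    with pytest.raises(ValueError, match="l"):
        csp_filters(cov_est(C1), cov_est(C2, 2), l=3)


def test_rcsp_alpha_zero_equals_csp(rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    K = random_spd(rng, 4)
    a = rcsp_filters(cov_est(C1), cov_est(C2, 2), K, K, alpha=0.0, l=2)
    b = csp_filters(cov_est(C1), cov_est(C2, 2), l=2)
    np.testing.assert_allclose(a.W, b.W, atol=1e-10)
    np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)


def test_tikhonov_closed_form_diagonal():
    # (C1, C2 + I) = (diag(4,1), diag(2,5)): eigenvalues 2 and 0.2; the top
    # filter is [1/sqrt(2), 0] after the w'(C2+aI)w = 1 scaling
    fs = rcsp_filters(
        cov_est(np.diag([4.0, 1.0]), 1), cov_est(np.diag([1.0, 4.0]), 2),
        None, None, alpha=1.0, l=1,
    )
    assert fs.eigenvalues[0] == pytest.approx(2.0)
    np.testing.assert_allclose(fs.W[0], [1 / np.sqrt(2), 0], atol=1e-12)
    # JP2 problem mirrors: (diag(1,4), diag(5,2)) -> top eigenvalue 2
    assert fs.eigenvalues[1] == pytest.approx(2.0)


def test_tikhonov_eigenvalues_strictly_decrease_in_alpha(rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    prev = None
    for alpha in [0.0, 0.5, 1.0, 2.0, 5.0]:
        fs = rcsp_filters(cov_est(C1), cov_est(C2, 2), None, None, alpha, l=2)
        jp1 = fs.eigenvalues[:2]
        if prev is not None:
            assert np.all(jp1 < prev)
        prev = jp1


def test_negative_alpha_and_bad_penalty_rejected(rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    with pytest.raises(ValueError, match="alpha"):
        rcsp_filters(cov_est(C1), cov_est(C2, 2), None, None, alpha=-1.0, l=1)
    with pytest.raises(ValueError, match="symmetric"):
        K = np.triu(np.ones((4, 4)))
        rcsp_filters(cov_est(C1), cov_est(C2, 2), K, K, alpha=1.0, l=1)


def test_trace_normalized_filters_scale_invariant(small_two_class):
    """Amplitude rescaling of all raw trials leaves the filters bit-identical."""
    sig, _ = small_two_class
    scaled = sig.subset(np.arange(sig.n_trials))
    scaled.data = sig.data * 2.0  # power of two: exact float scaling
    for s, t in [(sig, scaled)]:
        C1a = class_covariance(s, 1, "trace_normalized_mean")
        C1b = class_covariance(t, 1, "trace_normalized_mean")
        np.testing.assert_array_equal(C1a.C, C1b.C)
    a = csp_filters(class_covariance(sig, 1), class_covariance(sig, 2), l=2)
    b = csp_filters(class_covariance(scaled, 1), class_covariance(scaled, 2), l=2)
    np.testing.assert_array_equal(a.W, b.W)


def test_filter_set_json_roundtrip(tmp_path, rng):
    C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
    fs = rcsp_filters(cov_est(C1), cov_est(C2, 2), None, None, 0.1, l=2)
    fs.channel_names = ["a", "b", "c", "d"]
    fs.save(tmp_path / "filters.json")
    back = type(fs).load(tmp_path / "filters.json")
    np.testing.assert_array_equal(back.W, fs.W)
    assert back.method == fs.method and back.alpha == fs.alpha
    assert back.channel_names == fs.channel_names
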