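"""Rayleigh-quotient optimality: brute-force oracles, back-transform
identities, independent generalized-eigenvalue route, alignment cosines."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from netinfospec import (
    LinearNetwork,
    fisher_trace,
    gamma_matrix,
    make_scale_free,
    optimal_uref,
    optimal_xref,
    steady_covariance,
)
from netinfospec.optima import alignment_cosine, rayleigh_refine, sign_fix


class TestOptimalXref:
    def test_trace_at_optimum_equals_lambda_max(self, ba20):
        x_opt, lam, prob = optimal_xref(ba20, 10.0)
        assert np.linalg.norm(x_opt) == pytest.approx(1.0)
        assert fisher_trace(ba20, x_opt, 10.0) == pytest.approx(lam, rel=1e-8)

    def test_random_search_bounded_and_refinable(self, ba20, rng):
        x_opt, lam, prob = optimal_xref(ba20, 10.0)
        G = gamma_matrix(ba20, 10.0)
        S = steady_covariance(ba20)
        X = rng.standard_normal((20_000, ba20.n))
        GB = G @ ba20.B
        num = np.einsum("ij,ij->i", X @ GB, X @ GB)
        den = np.einsum("ij,ij->i", X @ S, X)
        vals = num / den
        assert vals.max() <= lam * (1 + 1e-10)
        # power iteration from the best sample reaches lambda_max
        best = X[np.argmax(vals)]
        v0 = prob.L.T @ best
        _, lam_ref = rayleigh_refine(prob.S, v0)
        assert lam_ref == pytest.approx(lam, rel=1e-6)

    def test_one_dimensional_trace_is_xref_independent(self):
        net = LinearNetwork(A=[[-2.0]], B=[[1.0]], Sigma_w=[[1.0]], n_d=1)
        _, lam, _ = optimal_xref(net, 10.0)
        for x in ([1.0], [-5.0], [0.3]):
            assert fisher_trace(net, x, 10.0) == pytest.approx(lam, rel=1e-12)

    def test_identity_covariance_reduces_to_plain_eigenproblem(self, rng):
        # Sigma_w = -2A makes Sigma_x = I exactly (symmetric stable A), so
        # the whitening is trivial and x_opt is the principal eigenvector
        # of Gamma B B^T Gamma^T
        base = make_scale_free(12, 4, seed=6)
        net = LinearNetwork(
            A=base.A, B=base.B, Sigma_w=-2.0 * base.A, n_d=base.n_d
        )
        assert np.allclose(steady_covariance(net), np.eye(12), atol=1e-12)
        x_opt, lam, _ = optimal_xref(net, 10.0)
        GB = gamma_matrix(net, 10.0) @ net.B
        w, V = np.linalg.eigh(GB @ GB.T)
        assert abs(abs(x_opt @ V[:, -1])) == pytest.approx(1.0, abs=1e-8)
        assert lam == pytest.approx(w[-1], rel=1e-10)

    def test_matches_generalized_eigensolver(self, ba20):
        # independent route: (Gamma B B^T Gamma^T) v = lambda Sigma_x v
        _, lam, prob = optimal_xref(ba20, 10.0)
        GB = gamma_matrix(ba20, 10.0) @ ba20.B
        w = scipy.linalg.eigh(GB @ GB.T, steady_covariance(ba20), eigvals_only=True)
        assert np.allclose(np.sort(w), np.sort(prob.eigenvalues), atol=1e-9 * max(1, lam))

    def test_whitened_quotient_equals_original_at_backtransform(self, ba20, rng):
        _, _, prob = optimal_xref(ba20, 10.0)
        GB = gamma_matrix(ba20, 10.0) @ ba20.B
        Sx = steady_covariance(ba20)
        for _ in range(10):
            xs = rng.standard_normal(ba20.n)
            white = (xs @ prob.S @ xs) / (xs @ xs)
            x = scipy.linalg.solve_triangular(prob.L.T, xs, lower=False)
            orig = (x @ GB @ GB.T @ x) / (x @ Sx @ x)
            assert white == pytest.approx(orig, rel=1e-10)


class TestOptimalUref:
    def test_unit_norm_and_consistency(self, ba20):
        u_opt, lam, prob = optimal_uref(ba20, 10.0)
        assert np.linalg.norm(u_opt) == pytest.approx(1.0)
        x_tilde = gamma_matrix(ba20, 10.0) @ ba20.B @ u_opt
        assert fisher_trace(ba20, x_tilde, 10.0) == pytest.approx(lam, rel=1e-8)

    def test_random_search_bounded_and_refinable(self, ba20, rng):
        u_opt, lam, prob = optimal_uref(ba20, 10.0)
        GB = gamma_matrix(ba20, 10.0) @ ba20.B
        Sx = steady_covariance(ba20)
        N = (GB.T @ GB) @ (GB.T @ GB)
        M = GB.T @ Sx @ GB
        U = rng.standard_normal((20_000, ba20.m))
        vals = np.einsum("ij,jk,ik->i", U, N, U) / np.einsum("ij,jk,ik->i", U, M, U)
        assert vals.max() <= lam * (1 + 1e-10)
        v0 = prob.L.T @ U[np.argmax(vals)]
        _, lam_ref = rayleigh_refine(prob.S, v0)
        assert lam_ref == pytest.approx(lam, rel=1e-6)

    def test_scalar_input_space(self):
        net = make_scale_free(8, 1, seed=2)
        u_opt, lam, _ = optimal_uref(net, 10.0)
        assert abs(u_opt[0]) == pytest.approx(1.0)
        x_tilde = gamma_matrix(net, 10.0) @ net.B @ np.array([1.0])
        assert fisher_trace(net, x_tilde, 10.0) == pytest.approx(lam, rel=1e-10)

    def test_denominator_positive_definite_for_controllable_fixture(self, ba20):
        GB = gamma_matrix(ba20, 10.0) @ ba20.B
        M = GB.T @ steady_covariance(ba20) @ GB
        assert np.linalg.eigvalsh((M + M.T) / 2).min() > 0

    def test_spectrum_dimension(self, ba20):
        _, _, prob = optimal_uref(ba20, 10.0)
        assert prob.eigenvalues.shape == (ba20.m,)
        assert prob.eigenvalues.min() >= -1e-10 * prob.eigenvalues.max()


class TestAlignmentCosine:
    def test_basic_identities(self, rng):
        v = rng.standard_normal(7)
        assert alignment_cosine(v, v) == pytest.approx(1.0)
        assert alignment_cosine(v, -v) == pytest.approx(1.0)
        e = np.eye(4)
        assert alignment_cosine(e[0], e[1]) == 0.0

    def test_subset_restriction(self):
        v1 = np.array([1.0, 0.0, 3.0])
        v2 = np.array([1.0, 5.0, 3.0])
        assert alignment_cosine(v1, v2, indices=np.array([0, 2])) == pytest.approx(1.0)

    def test_zero_subvector_rejected(self):
        with pytest.raises(ValueError):
            alignment_cosine(np.array([0.0, 1.0]), np.ones(2), indices=np.array([0]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal((2, 5))
        c = alignment_cosine(a, b)
        assert 0.0 <= c <= 1.0


def test_sign_fix_largest_component_positive(rng):
    v = rng.standard_normal(9)
    f = sign_fix(v)
    assert f[np.argmax(np.abs(f))] > 0
    assert np.array_equal(sign_fix(-v), f)


@pytest.mark.parametrize("seed", range(5))
def test_rayleigh_bracketing_many_networks(seed, rng):
    net = make_scale_free(15, 4, seed=seed)
    _, lam, prob = optimal_xref(net, 10.0)
    G = gamma_matrix(net, 10.0)
    Sx = steady_covariance(net)
    for _ in range(200):
        tr = fisher_trace(net, rng.standard_normal(net.n), gamma=G, sigma_x=Sx)
        assert prob.lambda_min - 1e-10 <= tr <= prob.lambda_max + 1e-10
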