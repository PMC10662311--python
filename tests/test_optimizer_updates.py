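"""Closed-form block updates versus independent oracles.

Each update is checked against a finite-difference (or grid) stationarity
oracle on small random instances: the update's output must be a stationary
point of the objective terms that depend on its block, with the other blocks
either held fixed or re-minimized (envelope argument) exactly as in the
closed-form derivation.
"""

import numpy as np
import pytest

from ldg.exceptions import InvalidParameterError
from ldg.local_domains import build_all_local_domains
from ldg.optimizer import (
    BinaryProblem,
    LDGHyperparams,
    LDGState,
    centering_matrix,
    compute_objective,
    matrix_inv_sqrt,
    matrix_sqrt,
    update_global_bias,
    update_global_model,
    update_lambda,
    update_local_bias,
    update_local_model,
    update_majorizer,
    update_pseudo_global,
    update_pseudo_local,
    update_theta,
)

HYPER = LDGHyperparams(alpha=0.7, beta=0.9, mu=1.3, k1=2, k2=2, k_graph=2, jitter=1e-9)


def make_instance(seed, d=3, n=8):
    """Small consistent instance: data, one active domain, fixed weights."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((d, n))
    y = np.concatenate((np.ones(n // 2), -np.ones(n - n // 2)))
    domains = build_all_local_domains(X, y, HYPER.k1, HYPER.k2, k_graph=HYPER.k_graph)
    dom = domains[rng.integers(len(domains))]
    W0 = rng.standard_normal((d, len(domains)))
    V = update_majorizer(W0, 1e-3)
    theta_v = float(rng.uniform(0.1, 0.9))
    lambda_v = float(rng.uniform(0.1, 0.9))
    f = rng.standard_normal(n)
    return X, y, domains, dom, V, theta_v, lambda_v, f


def assemble_Q(dom, theta_v, V, hyper=HYPER):
    Xv = dom.data_block
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    return (
        theta_v ** hyper.r * (Xc @ Xc.T)
        + Xv @ Xv.T
        + hyper.beta * V
        + hyper.alpha * np.eye(Xv.shape[0])
    )


def assemble_A(X, dom, Q, lambda_v, hyper=HYPER):
    Xv = dom.data_block
    Xcg = X - X.mean(axis=1, keepdims=True)
    Sv = Xv @ Xv.T
    Gv = Xv @ dom.laplacian @ Xv.T
    return (
        Xcg @ Xcg.T
        - Sv @ np.linalg.solve(Q, Sv)
        + Sv
        + hyper.beta * np.eye(X.shape[0])
        + lambda_v * Gv
    )


def assemble_B(dom, Q, A, theta_v, hyper=HYPER):
    Xv = dom.data_block
    k = Xv.shape[1]
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    Sv = Xv @ Xv.T
    th_r, th_2r = theta_v ** hyper.r, theta_v ** (2 * hyper.r)
    T2 = Xc.T @ np.linalg.solve(Q, Sv)
    return (
        th_r * centering_matrix(k)
        - th_2r * (T2 @ np.linalg.solve(A, T2.T))
        - th_2r * (Xc.T @ np.linalg.solve(Q, Xc))
    )


def local_terms(w_v, dom, f_v, theta_v, w_tilde, V, hyper=HYPER):
    """All objective terms that involve w_v (bias eliminated, trace norm
    majorized by the quadratic form in V)."""
    Xv = dom.data_block
    c = Xv.T @ w_v - f_v
    c = c - c.mean()
    return (
        theta_v ** hyper.r * float(c @ c)
        + hyper.alpha * float(w_v @ w_v)
        + float(np.sum((Xv.T @ (w_v - w_tilde)) ** 2))
        + hyper.beta * float(w_v @ V @ w_v)
    )


def global_terms(w_tilde, X, dom, f, lambda_v, hyper=HYPER):
    """w_tilde-only terms (bias eliminated, Laplacian restricted to the
    active domain as in the per-domain update)."""
    Xv = dom.data_block
    z = Xv.T @ w_tilde
    g = X.T @ w_tilde - f
    g = g - g.mean()
    return (
        lambda_v * float(z @ dom.laplacian @ z)
        + float(g @ g)
        + hyper.beta * float(w_tilde @ w_tilde)
    )


def fd_gradient(fun, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


class TestCenteringMatrix:
    def test_annihilates_constants_and_removes_mean(self):
        np.testing.assert_allclose(centering_matrix(2) @ np.ones(2), 0.0, atol=1e-15)
        np.testing.assert_allclose(
            centering_matrix(3) @ np.array([1.0, 2.0, 3.0]),
            [-1.0, 0.0, 1.0],
            atol=1e-14,
        )

    def test_idempotent(self):
        H = centering_matrix(5)
        np.testing.assert_allclose(H @ H, H, atol=1e-14)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(InvalidParameterError):
            centering_matrix(0)


class TestBiasUpdates:
    def test_constant_pseudo_labels(self):
        Xv = np.random.default_rng(0).standard_normal((3, 4))
        assert update_local_bias(np.zeros(3), Xv, np.full(4, 2.5)) == pytest.approx(2.5)
        X = np.random.default_rng(1).standard_normal((3, 6))
        assert update_global_bias(np.zeros(3), X, np.full(6, -1.5)) == pytest.approx(-1.5)

    def test_centered_inputs_give_zero(self, rng):
        Xv = rng.standard_normal((3, 5))
        Xv -= Xv.mean(axis=1, keepdims=True)
        f_v = rng.standard_normal(5)
        f_v -= f_v.mean()
        w = rng.standard_normal(3)
        assert update_local_bias(w, Xv, f_v) == pytest.approx(0.0, abs=1e-12)
        assert update_global_bias(w, Xv, f_v) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Xv = rng.standard_normal((3, 6))
        w = rng.standard_normal(3)
        f_v = rng.standard_normal(6)
        b = update_local_bias(w, Xv, f_v)

        def loss(bb):
            r = Xv.T @ w + bb - f_v
            return r @ r

        grid = b + np.linspace(-1.0, 1.0, 2001)
        assert loss(b) <= np.min([loss(bb) for bb in grid]) + 1e-12


class TestMajorizer:
    def test_identity_limit(self):
        # W = I_d gives WW^T = I, so V = (I)^{-1/2} = I at jitter 0
        np.testing.assert_allclose(update_majorizer(np.eye(4), 0.0), np.eye(4), atol=1e-12)

    def test_orthogonal_columns_spectrum(self, rng):
        Qmat, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        s = np.array([2.0, 0.5])
        W = Qmat[:, :2] * s
        jit = 1e-4
        V = update_majorizer(W, jit)
        expected = np.sort(
            np.concatenate(((s ** 2 + jit) ** -0.5, np.full(3, jit ** -0.5)))
        )
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(V)), expected, rtol=1e-8)

    def test_symmetric_positive_definite(self, rng):
        V = update_majorizer(rng.standard_normal((4, 7)), 1e-6)
        np.testing.assert_allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() > 0


class TestSimplexUpdates:
    def test_theta_equal_residuals_uniform(self):
        np.testing.assert_allclose(update_theta(np.full(5, 3.0)), np.full(5, 0.2))

    def test_theta_direct_evaluation(self):
        np.testing.assert_allclose(
            update_theta(np.array([1.0, 2.0])), [2.0 / 3.0, 1.0 / 3.0], rtol=1e-9
        )

    def test_theta_simplex_and_permutation_equivariance(self, rng):
        res = rng.uniform(0.1, 5.0, size=6)
        th = update_theta(res)
        assert th.sum() == pytest.approx(1.0)
        perm = rng.permutation(6)
        np.testing.assert_allclose(update_theta(res[perm]), th[perm])

    def test_lambda_equal_traces_uniform(self, small_binary):
        X, y = small_binary
        domains = build_all_local_domains(X, y, 2, 2, k_graph=2)
        lam = update_lambda(np.zeros(X.shape[0]), domains, mu=1.0)
        np.testing.assert_allclose(lam, np.full(len(domains), 1.0 / len(domains)))

    def test_lambda_direct_evaluation(self):
        # traces (0, mu): weights (1, e^{-1}) normalized
        from ldg.optimizer import _lambda_from_traces

        lam = _lambda_from_traces(np.array([0.0, 1.3]), mu=1.3)
        e1 = np.exp(-1.0)
        np.testing.assert_allclose(lam, [1 / (1 + e1), e1 / (1 + e1)], rtol=1e-9)

    def test_lambda_large_mu_tends_uniform(self, small_binary):
        X, y = small_binary
        domains = build_all_local_domains(X, y, 2, 2, k_graph=2)
        w = np.random.default_rng(0).standard_normal(X.shape[0])
        lam = update_lambda(w, domains, mu=1e9)
        np.testing.assert_allclose(lam, np.full(len(domains), 1.0 / len(domains)), atol=1e-6)


class TestObjective:
    def _zero_state(self, X, y, domains):
        d, n = X.shape
        m = len(domains)
        return LDGState(
            W=np.zeros((d, m)),
            w_tilde=np.zeros(d),
            b_local=np.zeros(m),
            b_global=0.0,
            f_global=y.astype(float).copy(),
            f_local=[np.zeros(dom.size) for dom in domains],
            theta=np.full(m, 1.0 / m),
            lambda_=np.full(m, 1.0 / m),
            V=np.eye(d),
        )

    def test_zero_model_closed_form(self, small_binary):
        X, y = small_binary
        domains = build_all_local_domains(X, y, 2, 2, k_graph=2)
        state = self._zero_state(X, y, domains)
        obj = compute_objective(state, BinaryProblem(X, y, domains), HYPER)
        m = len(domains)
        assert obj == pytest.approx(float(y @ y) - HYPER.mu * np.log(m), rel=1e-12)

    def test_permutation_invariance(self, small_binary, rng):
        X, y = small_binary
        domains = build_all_local_domains(X, y, 2, 2, k_graph=2)
        m = len(domains)
        d = X.shape[0]
        state = self._zero_state(X, y, domains)
        state.W = rng.standard_normal((d, m))
        state.w_tilde = rng.standard_normal(d)
        state.b_local = rng.standard_normal(m)
        state.f_local = [rng.standard_normal(dom.size) for dom in domains]
        theta = rng.uniform(0.1, 1.0, m)
        state.theta = theta / theta.sum()
        lam = rng.uniform(0.1, 1.0, m)
        state.lambda_ = lam / lam.sum()
        base = compute_objective(state, BinaryProblem(X, y, domains), HYPER)

        perm = rng.permutation(m)
        pstate = self._zero_state(X, y, domains)
        pstate.W = state.W[:, perm]
        pstate.w_tilde = state.w_tilde
        pstate.b_local = state.b_local[perm]
        pstate.f_local = [state.f_local[i] for i in perm]
        pstate.theta = state.theta[perm]
        pstate.lambda_ = state.lambda_[perm]
        pstate.f_global = state.f_global
        permuted = compute_objective(
            pstate, BinaryProblem(X, y, [domains[i] for i in perm]), HYPER
        )
        assert permuted == pytest.approx(base, rel=1e-10)

    def test_termwise_oracle(self, rng):
        """Independent term-by-term recomputation, including the SVD trace norm."""
        X, y, domains, _, _, _, _, _ = make_instance(3, d=3, n=8)
        m = len(domains)
        state = self._zero_state(X, y, domains)
        state.W = rng.standard_normal((3, m))
        state.w_tilde = rng.standard_normal(3)
        state.b_local = rng.standard_normal(m)
        state.b_global = 0.3
        state.f_global = rng.standard_normal(8)
        state.f_local = [rng.standard_normal(dom.size) for dom in domains]
        th = rng.uniform(0.1, 1, m)
        state.theta = th / th.sum()
        lm = rng.uniform(0.1, 1, m)
        state.lambda_ = lm / lm.sum()

        expected = 0.0
        for v, dom in enumerate(domains):
            Xv = dom.data_block
            rv = Xv.T @ state.W[:, v] + state.b_local[v] - state.f_local[v]
            expected += state.theta[v] ** HYPER.r * rv @ rv
            expected += HYPER.alpha * state.W[:, v] @ state.W[:, v]
            av = Xv.T @ state.W[:, v] - Xv.T @ state.w_tilde
            expected += av @ av
            z = Xv.T @ state.w_tilde
            expected += state.lambda_[v] * z @ dom.laplacian @ z
        g = X.T @ state.w_tilde + state.b_global - state.f_global
        expected += g @ g + (state.f_global - y) @ (state.f_global - y)
        expected += HYPER.beta * (
            np.linalg.svd(state.W, compute_uv=False).sum()
            + state.w_tilde @ state.w_tilde
        )
        expected += HYPER.mu * np.sum(state.lambda_ * np.log(state.lambda_))
        got = compute_objective(state, BinaryProblem(X, y, domains), HYPER)
        assert got == pytest.approx(float(expected), rel=1e-12)


class TestLocalModelUpdate:
    def test_zero_inputs_give_zero(self):
        _, _, _, dom, V, th, _, _ = make_instance(0)
        w = update_local_model(
            dom.data_block, np.zeros(dom.size), np.zeros(3), th, V, HYPER
        )
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_huge_ridge_shrinks_to_zero(self):
        _, _, _, dom, V, th, _, _ = make_instance(1)
        hyper = LDGHyperparams(alpha=1e8, beta=HYPER.beta, mu=1.0, k1=2, k2=2, k_graph=2)
        f_v = np.ones(dom.size)
        w = update_local_model(dom.data_block, f_v, np.ones(3), th, V, hyper)
        assert np.linalg.norm(w) < 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_finite_difference_stationarity(self, seed):
        _, _, _, dom, V, th, _, _ = make_instance(seed)
        rng = np.random.default_rng(seed + 100)
        f_v = rng.standard_normal(dom.size)
        wt = rng.standard_normal(3)
        w = update_local_model(dom.data_block, f_v, wt, th, V, HYPER)
        grad = fd_gradient(lambda ww: local_terms(ww, dom, f_v, th, wt, V), w)
        assert np.linalg.norm(grad) <= 1e-6


class TestGlobalModelUpdate:
    def test_zero_inputs_give_zero(self):
        X, _, _, dom, V, th, lam, _ = make_instance(0)
        Q = assemble_Q(dom, th, V)
        wt = update_global_model(
            X, np.zeros(X.shape[1]), dom.data_block, np.zeros(dom.size),
            Q, th, lam, dom.laplacian, HYPER,
        )
        np.testing.assert_allclose(wt, 0.0, atol=1e-12)

    def test_huge_beta_shrinks_to_zero(self):
        X, _, _, dom, V, th, lam, f = make_instance(1)
        hyper = LDGHyperparams(alpha=0.7, beta=1e8, mu=1.0, k1=2, k2=2, k_graph=2)
        Q = assemble_Q(dom, th, V, hyper)
        wt = update_global_model(
            X, f, dom.data_block, np.ones(dom.size), Q, th, lam, dom.laplacian, hyper
        )
        assert np.linalg.norm(wt) < 1e-5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_finite_difference_stationarity(self, seed):
        """Envelope oracle: w_v is re-minimized at every probe of w_tilde."""
        X, _, _, dom, V, th, lam, f = make_instance(seed)
        rng = np.random.default_rng(seed + 200)
        f_v = rng.standard_normal(dom.size)
        Q = assemble_Q(dom, th, V)
        wt = update_global_model(
            X, f, dom.data_block, f_v, Q, th, lam, dom.laplacian, HYPER
        )

        def total(w_tilde):
            w_v = update_local_model(dom.data_block, f_v, w_tilde, th, V, HYPER)
            return local_terms(w_v, dom, f_v, th, w_tilde, V) + global_terms(
                w_tilde, X, dom, f, lam
            )

        assert np.linalg.norm(fd_gradient(total, wt)) <= 1e-6


class TestPseudoLocalUpdate:
    def test_zero_global_labels_give_zero(self):
        X, _, _, dom, V, th, lam, _ = make_instance(0)
        Q = assemble_Q(dom, th, V)
        A = assemble_A(X, dom, Q, lam)
        f_v = update_pseudo_local(X, dom.data_block, np.zeros(X.shape[1]), Q, A, th, HYPER)
        np.testing.assert_allclose(f_v, 0.0, atol=1e-12)

    def test_constants_in_null_space(self):
        X, _, _, dom, V, th, lam, _ = make_instance(1)
        Q = assemble_Q(dom, th, V)
        A = assemble_A(X, dom, Q, lam)
        B = assemble_B(dom, Q, A, th)
        np.testing.assert_allclose(B @ np.ones(dom.size), 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_projected_finite_difference_stationarity(self, seed):
        X, _, _, dom, V, th, lam, f = make_instance(seed)
        Q = assemble_Q(dom, th, V)
        A = assemble_A(X, dom, Q, lam)
        f_v = update_pseudo_local(X, dom.data_block, f, Q, A, th, HYPER)

        def total(fv):
            wt = update_global_model(
                X, f, dom.data_block, fv, Q, th, lam, dom.laplacian, HYPER, A_v=A
            )
            w_v = update_local_model(dom.data_block, fv, wt, th, V, HYPER, Q_v=Q)
            return local_terms(w_v, dom, fv, th, wt, V) + global_terms(
                wt, X, dom, f, lam
            )

        grad = fd_gradient(total, f_v)
        grad -= grad.mean()  # project onto the centered subspace
        assert np.linalg.norm(grad) <= 1e-6


class TestPseudoGlobalUpdate:
    def test_single_sample_returns_label(self):
        # n = 1: the centering matrix vanishes and the system is the identity.
        hyper = LDGHyperparams(k1=1, k2=1, k_graph=1)
        X = np.array([[1.0], [2.0]])
        Xv = np.array([[0.5, 1.0], [0.2, -0.3]])
        Q = np.eye(2)
        A = np.eye(2)
        B = 0.5 * centering_matrix(2)
        f = update_pseudo_global(X, Xv, np.array([1.0]), Q, A, B, 0.5, hyper)
        np.testing.assert_allclose(f, [1.0])

    def test_zero_features_sherman_morrison(self):
        """X = 0 collapses the system to (I + H_n); f = y/2 for mean-zero y."""
        n, d = 8, 3
        X = np.zeros((d, n))
        Xv = np.zeros((d, 4))
        Q = np.eye(d)
        A = HYPER.beta * np.eye(d)
        B = 0.5 ** HYPER.r * centering_matrix(4)
        y = np.concatenate((np.ones(4), -np.ones(4)))
        f = update_pseudo_global(X, Xv, y, Q, A, B, 0.5, HYPER)
        np.testing.assert_allclose(f, y / 2.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_finite_difference_stationarity(self, seed):
        X, y, _, dom, V, th, lam, _ = make_instance(seed)
        Q = assemble_Q(dom, th, V)
        A = assemble_A(X, dom, Q, lam)
        B = assemble_B(dom, Q, A, th)
        f = update_pseudo_global(X, dom.data_block, y, Q, A, B, th, HYPER)

        def total(ff):
            f_v = update_pseudo_local(X, dom.data_block, ff, Q, A, th, HYPER)
            wt = update_global_model(
                X, ff, dom.data_block, f_v, Q, th, lam, dom.laplacian, HYPER, A_v=A
            )
            w_v = update_local_model(dom.data_block, f_v, wt, th, V, HYPER, Q_v=Q)
            return (
                local_terms(w_v, dom, f_v, th, wt, V)
                + global_terms(wt, X, dom, ff, lam)
                + float((ff - y) @ (ff - y))
            )

        assert np.linalg.norm(fd_gradient(total, f)) <= 1e-6

    def test_woodbury_matches_dense_path(self):
        """The large-n Woodbury solve equals the assembled dense system."""
        X, y, _, dom, V, th, lam, _ = make_instance(2, d=3, n=90)
        Q = assemble_Q(dom, th, V)
        A = assemble_A(X, dom, Q, lam)
        B = assemble_B(dom, Q, A, th)
        f_fast = update_pseudo_global(X, dom.data_block, y, Q, A, B, th, HYPER)
        # dense oracle
        n, d = X.shape[1], X.shape[0]
        Xc = X - X.mean(axis=1, keepdims=True)
        P = Xc.T
        Bp = np.linalg.pinv(B, hermitian=True, rcond=1e-8)
        Ainv = np.linalg.inv(A)
        Sv = dom.data_block @ dom.data_block.T
        Xvc = dom.data_block - dom.data_block.mean(axis=1, keepdims=True)
        R = Ainv @ Sv @ np.linalg.solve(Q, Xvc)
        G = Ainv + th ** (2 * HYPER.r) * R @ Bp @ R.T
        M = np.eye(n) + centering_matrix(n) - P @ G @ P.T
        np.testing.assert_allclose(f_fast, np.linalg.solve(M, y), atol=1e-8)


class TestMatrixMajorizationInequality:
    def test_majorization_inequality_random_pd_pairs(self):
        """0.5 tr(M V^{-1/2}) - tr(M^{1/2}) >= 0.5 tr(V V^{-1/2}) - tr(V^{1/2})."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            d = int(rng.integers(2, 6))
            A = rng.standard_normal((d, d))
            Bm = rng.standard_normal((d, d))
            M = A @ A.T + 0.1 * np.eye(d)
            Vt = Bm @ Bm.T + 0.1 * np.eye(d)
            lhs = 0.5 * np.trace(M @ matrix_inv_sqrt(Vt)) - np.trace(matrix_sqrt(M))
            rhs = 0.5 * np.trace(Vt @ matrix_inv_sqrt(Vt)) - np.trace(matrix_sqrt(Vt))
            assert lhs >= rhs - 1e-8
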