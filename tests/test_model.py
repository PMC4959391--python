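import numpy as np
import pytest

from o2pls import (
    PairedData,
    fit_o2pls,
    inner_relations,
    joint_svd,
    low_dimensional_design,
    predict,
    sign_correct,
    simulate_dataset,
)
from o2pls.model import (
    DegenerateScoresError,
    InsufficientRankError,
    InvalidComponentCountError,
    NoOrthogonalVariationError,
    NotCenteredError,
    O2PLSModel,
    extract_orthogonal,
)

from conftest import make_paired, principal_angle


class TestJointSVD:
    def test_diagonal_matrix_forces_axes(self):
        S = np.array([[3.0, 0.0], [0.0, 1.0]])
        W, C, d = joint_svd(S, 1)
        np.testing.assert_allclose(W[:, 0], [1, 0], atol=1e-14)
        np.testing.assert_allclose(C[:, 0], [1, 0], atol=1e-14)
        np.testing.assert_allclose(d, [3.0])
        W2, C2, d2 = joint_svd(S, 2)
        np.testing.assert_allclose(d2, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(W2), np.eye(2), atol=1e-14)

    def test_bilinear_form_bounded_by_top_singular_value(self, rng):
        """No random unit pair beats d1; alternating maximization attains it."""
        S = rng.normal(size=(5, 4))
        W, C, d = joint_svd(S, 1)
        w = rng.normal(size=(10**5, 5))
        c = rng.normal(size=(10**5, 4))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        vals = np.einsum("ip,pq,iq->i", w, S, c)
        assert vals.max() <= d[0] + 1e-10
        # independent oracle: alternating maximization of w'Sc from a
        # random start converges to the top singular pair
        w0 = rng.normal(size=5)
        for _ in range(200):
            c0 = S.T @ w0
            c0 /= np.linalg.norm(c0)
            w0 = S @ c0
            w0 /= np.linalg.norm(w0)
        assert abs(abs(w0 @ W[:, 0]) - 1) < 1e-10
        assert abs(float(w0 @ S @ c0) - d[0]) < 1e-8

    def test_sign_convention_and_errors(self, rng):
        S = rng.normal(size=(6, 4))
        W, C, d = joint_svd(S, 3)
        for j in range(3):
            # W anchors the pair sign; the pair covariance stays positive
            assert W[np.argmax(np.abs(W[:, j])), j] > 0
            assert W[:, j] @ S @ C[:, j] == pytest.approx(d[j], abs=1e-10)
        with pytest.raises(InvalidComponentCountError):
            joint_svd(S, 5)
        with pytest.raises(ValueError):
            joint_svd(np.array([[np.nan, 1.0]]), 1)


class TestExtractOrthogonal:
    def test_rank_one_case_is_analytic(self, rng):
        t = rng.normal(size=(30, 1))
        residual = t @ np.array([[3.0, 4.0]])
        W_orth, T_orth = extract_orthogonal(residual, t, 1)
        np.testing.assert_allclose(W_orth[:, 0], [0.6, 0.8], atol=1e-12)
        np.testing.assert_allclose(T_orth, residual @ W_orth, atol=1e-12)

    def test_orthogonal_residual_signals_no_variation(self, rng):
        scores = np.column_stack([np.ones(10), np.zeros(10)])
        residual = np.outer(np.r_[np.ones(5), -np.ones(5)], [1.0, 2.0, 3.0])
        assert np.abs(residual.T @ scores).max() < 1e-12
        with pytest.raises(NoOrthogonalVariationError):
            extract_orthogonal(residual, scores, 1)

    def test_matches_eigendecomposition_oracle(self, rng):
        residual = rng.normal(size=(50, 8))
        scores = rng.normal(size=(50, 2))
        W_orth, _ = extract_orthogonal(residual, scores, 2)
        M = residual.T @ scores
        evals, evecs = np.linalg.eigh(M @ M.T)
        order = np.argsort(evals)[::-1]
        for j in range(2):
            v = evecs[:, order[j]]
            angle = np.arccos(np.clip(abs(v @ W_orth[:, j]), -1, 1))
            # eigh works on the squared matrix, halving the attainable digits
            assert angle < 1e-7

    def test_insufficient_rank(self, rng):
        residual = rng.normal(size=(20, 5))
        scores = rng.normal(size=(20, 1))
        with pytest.raises(InsufficientRankError):
            extract_orthogonal(residual, scores, 2)


class TestInnerRelations:
    def test_exact_linear_link(self, rng):
        T = rng.normal(size=(40, 1))
        B_T, B_U, H_UT, H_TU, r2_ut, r2_tu = inner_relations(T, 2 * T)
        np.testing.assert_allclose(B_T, [[2.0]], atol=1e-12)
        np.testing.assert_allclose(H_UT, np.zeros_like(T), atol=1e-12)
        assert r2_ut == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_scores_give_zero(self):
        T = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        U = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        B_T, *_, r2_ut, r2_tu = inner_relations(T, U)
        assert abs(B_T[0, 0]) < 1e-14
        assert r2_ut < 1e-14

    def test_matches_normal_equations_oracle(self, rng):
        T = rng.normal(size=(100, 2))
        U = rng.normal(size=(100, 2))
        B_T, B_U, *_ = inner_relations(T, U)
        np.testing.assert_allclose(B_T, np.linalg.solve(T.T @ T, T.T @ U), atol=1e-10)
        np.testing.assert_allclose(B_U, np.linalg.solve(U.T @ U, U.T @ T), atol=1e-10)

    def test_degenerate_scores_rejected(self, rng):
        T = np.zeros((10, 1))
        with pytest.raises(DegenerateScoresError):
            inner_relations(T, np.ones((10, 1)))


class TestFit:
    def test_zero_noise_recovers_signal_subspaces(self):
        design = low_dimensional_design(alpha=0.0)
        design.N = 200
        data, truth = simulate_dataset(design, seed=5)
        model = fit_o2pls(data.center(), 1, 1, 1)
        Xc = data.center().X
        assert (model.E**2).sum() / (Xc**2).sum() < 1e-10
        angle_x = principal_angle(
            np.hstack([model.W, model.P_Yorth]), np.hstack([truth.W, truth.P_Yorth])
        )
        angle_y = principal_angle(
            np.hstack([model.C, model.P_Xorth]), np.hstack([truth.C, truth.P_Xorth])
        )
        assert angle_x < 1e-6
        assert angle_y < 1e-6

    def test_pls_limit_equals_single_svd(self, small_pair):
        """With no orthogonal components the fit is one SVD of X'Y."""
        model = fit_o2pls(small_pair, 2, 0, 0)
        U, d, Vt = np.linalg.svd(small_pair.X.T @ small_pair.Y)
        for j in range(2):
            flip = np.sign(U[np.argmax(np.abs(U[:, j])), j])
            np.testing.assert_allclose(model.W[:, j], flip * U[:, j], atol=1e-12)
            np.testing.assert_allclose(model.C[:, j], flip * Vt[j], atol=1e-12)
        np.testing.assert_allclose(model.T, small_pair.X @ model.W, atol=1e-12)
        np.testing.assert_allclose(model.singular_values, d[:2], atol=1e-12)

    def test_single_replicate_loading_recovery(self):
        data, truth = simulate_dataset(low_dimensional_design(0.05), seed=7)
        model = fit_o2pls(data.center(), 1, 1, 1)
        W_hat = sign_correct(model.W, truth.W)
        assert np.abs(W_hat - truth.W).max() < 0.05

    def test_model_invariants(self, lowdim_data):
        data, _ = lowdim_data
        m = fit_o2pls(data, 1, 1, 1)
        for M in (m.W, m.C, m.W_Yorth, m.C_Xorth):
            G = M.T @ M
            assert np.abs(G - np.eye(G.shape[0])).max() < 1e-10
        assert np.all(np.diff(m.singular_values) <= 0)
        # reconstruction identities
        X_rec = m.T @ m.W.T + m.T_Yorth @ m.P_Yorth.T + m.E
        Y_rec = m.U @ m.C.T + m.U_Xorth @ m.P_Xorth.T + m.F
        assert np.abs(X_rec - data.X).max() < 1e-8 * np.abs(data.X).max()
        assert np.abs(Y_rec - data.Y).max() < 1e-8 * np.abs(data.Y).max()
        np.testing.assert_allclose(m.H_UT, m.U - m.T @ m.B_T, atol=1e-14)
        np.testing.assert_allclose(m.H_TU, m.T - m.U @ m.B_U, atol=1e-14)

    def test_eigen_equation_of_orthogonal_direction(self, lowdim_data):
        data, _ = lowdim_data
        m = fit_o2pls(data, 1, 1, 1)
        T0 = data.X @ m.W_provisional
        E0 = data.X - T0 @ m.W_provisional.T
        A = E0.T @ T0 @ T0.T @ E0
        w = m.W_Yorth[:, 0]
        lam = float(w @ A @ w)
        assert np.linalg.norm(A @ w - lam * w) / lam < 1e-8

    def test_uncentered_input_refused(self, rng):
        data = make_paired(rng)
        shifted = PairedData(
            X=data.X + 5.0,
            Y=data.Y,
            sample_ids=data.sample_ids,
            x_var_ids=data.x_var_ids,
            y_var_ids=data.y_var_ids,
        )
        with pytest.raises(NotCenteredError):
            fit_o2pls(shifted, 1, 0, 0)

    @pytest.mark.parametrize("a,nx,ny", [(0, 0, 0), (7, 0, 0), (1, 8, 0), (1, 0, 6)])
    def test_component_bounds(self, small_pair, a, nx, ny):
        with pytest.raises(InvalidComponentCountError):
            fit_o2pls(small_pair, a, nx, ny)

    def test_widened_provisional_subspace_allows_more_orthogonal(self, lowdim_data):
        """More block-specific than shared components needs widening."""
        data, _ = lowdim_data
        with pytest.raises(InsufficientRankError):
            fit_o2pls(data, 1, 0, 3)
        m = fit_o2pls(data, 1, 0, 3, provisional_components=3)
        assert m.C_Xorth.shape == (50, 3)
        G = m.C_Xorth.T @ m.C_Xorth
        assert np.abs(G - np.eye(3)).max() < 1e-10


class TestPredict:
    def test_zero_inner_relation_predicts_means(self, small_pair):
        m = fit_o2pls(small_pair, 1, 0, 0)
        m.B_T[:] = 0.0
        means = (np.full(8, 1.5), np.full(6, -2.0))
        pred = predict(m, np.ones((3, 8)), "x_to_y", means=means)
        np.testing.assert_allclose(pred, np.full((3, 6), -2.0), atol=1e-12)

    def test_hand_computed_single_component(self):
        p, q = 4, 3
        W = np.zeros((p, 1)); W[0, 0] = 1.0
        C = np.zeros((q, 1)); C[0, 0] = 1.0
        m = O2PLSModel(
            a=1, n_x=0, n_y=0, W=W, C=C,
            T=np.zeros((2, 1)), U=np.zeros((2, 1)),
            W_Yorth=np.zeros((p, 0)), P_Yorth=np.zeros((p, 0)),
            T_Yorth=np.zeros((2, 0)), C_Xorth=np.zeros((q, 0)),
            P_Xorth=np.zeros((q, 0)), U_Xorth=np.zeros((2, 0)),
            B_T=np.array([[2.0]]), B_U=np.array([[0.5]]),
            E=np.zeros((2, p)), F=np.zeros((2, q)),
            H_UT=np.zeros((2, 1)), H_TU=np.zeros((2, 1)),
            singular_values=np.array([1.0]),
            r2_u_on_t=1.0, r2_t_on_u=1.0,
            column_means_x=np.zeros(p), column_means_y=np.zeros(q),
        )
        x = np.array([[3.0, 0.0, 0.0, 0.0]])
        pred = predict(m, x, "x_to_y")
        np.testing.assert_allclose(pred, [[6.0, 0.0, 0.0]], atol=1e-14)

    def test_zero_noise_two_way_prediction(self):
        design = low_dimensional_design(alpha=0.0)
        data, truth = simulate_dataset(design, seed=9)
        dc = data.center()
        m = fit_o2pls(dc, 1, 1, 1)
        y_signal = truth.U @ truth.C.T  # the predictable part of Y
        y_hat = predict(m, data.X, "x_to_y", means=(dc.column_means_x, dc.column_means_y))
        resid = y_hat - dc.column_means_y - (y_signal - y_signal.mean(axis=0))
        # the joint/orthogonal split itself carries an O(1/sqrt(N)) rotation
        # from finite-sample score correlations, so training prediction of the
        # true joint part is accurate to that order, not machine precision
        assert (resid**2).mean() / (y_signal**2).mean() < 5e-3

    def test_shape_and_direction_errors(self, small_pair):
        m = fit_o2pls(small_pair, 1, 0, 0)
        with pytest.raises(ValueError):
            predict(m, np.ones((2, 5)), "x_to_y")
        with pytest.raises(ValueError):
            predict(m, np.ones((2, 8)), "sideways")
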