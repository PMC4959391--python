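"""The O2PLS decomposition: joint, orthogonal and noise parts of two blocks.

The model decomposes two centered, sample-aligned matrices as

    X = T W' + T_Yorth P_Yorth' + E
    Y = U C' + U_Xorth P_Xorth' + F

with inner relations U = T B_T + H_UT and T = U B_U + H_TU linking the joint
scores of the two blocks.  The joint loadings W, C are the leading singular
vectors of the cross-product X'Y — the directions maximizing the covariance
between block scores t = Xw and u = Yc.  Orthogonal loadings are the leading
left-singular vectors of the residual-score cross-products E0'T and F0'U:
systematic variation within one block that overlaps the provisional joint
scores but is unrelated to the other block.

Fitting pipeline (``fit_o2pls``): provisional joint SVD; extraction and
deflation of the orthogonal parts of each block; a second joint SVD on the
deflated cross-product so the final joint part is corrected for orthogonal
variation; inner-relation least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PairedData

__all__ = [
    "O2PLSModel",
    "joint_svd",
    "extract_orthogonal",
    "inner_relations",
    "fit_o2pls",
    "predict",
    "InvalidComponentCountError",
    "NotCenteredError",
    "NoOrthogonalVariationError",
    "InsufficientRankError",
    "DegenerateScoresError",
]

#: relative singular-value cutoff for pseudo-inverses and rank decisions
PINV_RCOND = 1e-12


class InvalidComponentCountError(ValueError):
    """Requested component numbers exceed what the data dimensions allow."""


class NotCenteredError(ValueError):
    """Fit requires column-mean centered blocks; input is visibly uncentered."""


class NoOrthogonalVariationError(RuntimeError):
    """Residual-score cross-product is numerically zero: no orthogonal part."""


class InsufficientRankError(ValueError):
    """More orthogonal components requested than the cross-product's rank."""


class DegenerateScoresError(ValueError):
    """A score column has zero variance; inner relations are undefined."""


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (in place safe copy)."""
    W = W.copy()
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def joint_svd(S: np.ndarray, a: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading singular triplets of a cross-product matrix.

    Parameters
    ----------
    S
        p x q cross-product matrix, typically X'Y of two centered blocks.
    a
        Number of joint components, 1 <= a <= min(p, q).

    Returns
    -------
    W, C, d
        First ``a`` left and right singular vectors (columns) and the
        corresponding non-increasing singular values.  For any unit vectors
        w, c the bilinear form w'Sc is bounded by d[0] and attained at the
        first pair.  Exact ties keep the smallest-index vectors of the
        decomposition.  Signs are fixed per (w, c) PAIR, anchored so each W
        column's largest-magnitude entry is positive; flipping the pair
        jointly keeps the covariance w_j'Sc_j = +d_j (an independent flip
        of one side would negate it).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("S must be a matrix")
    if not np.isfinite(S).all():
        raise ValueError("cross-product matrix contains non-finite values")
    if not 1 <= a <= min(S.shape):
        raise InvalidComponentCountError(
            f"a={a} outside [1, min(p, q)={min(S.shape)}]"
        )
    U, d, Vt = np.linalg.svd(S, full_matrices=False)
    W = U[:, :a].copy()
    C = Vt[:a].T.copy()
    for j in range(a):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
            C[:, j] = -C[:, j]
    return W, C, d[:a].copy()


def extract_orthogonal(
    residual: np.ndarray, scores: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Directions of residual variation that overlap the joint scores.

    ``residual`` is data minus its joint approximation (e.g. E0 = X - TW');
    the orthogonal loadings are the first ``n`` left-singular vectors of
    residual' scores — equivalently the top eigenvectors of
    residual' scores scores' residual — and the orthogonal scores are the
    residual projected on them.

    Returns
    -------
    W_orth, T_orth
        m x n orthonormal loadings (sign-fixed) and N x n scores
        T_orth = residual @ W_orth.

    Raises
    ------
    NoOrthogonalVariationError
        If residual'scores is numerically zero (Frobenius norm < 1e-12);
        callers treat this as "use zero orthogonal components".
    InsufficientRankError
        If ``n`` exceeds the rank of residual'scores.
    """
    residual = np.asarray(residual, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if residual.shape[0] != scores.shape[0]:
        raise ValueError("residual and scores must have the same number of rows")
    if not 1 <= n <= residual.shape[1]:
        raise InvalidComponentCountError(f"n={n} outside [1, {residual.shape[1]}]")
    M = residual.T @ scores
    if np.linalg.norm(M) < 1e-12:
        raise NoOrthogonalVariationError(
            "no detectable orthogonal variation (residual'scores ~ 0)"
        )
    U, d, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(d > d[0] * PINV_RCOND))
    if n > rank:
        raise InsufficientRankError(
            f"requested {n} orthogonal components but residual'scores has rank {rank}"
        )
    W_orth = _fix_signs(U[:, :n])
    T_orth = residual @ W_orth
    return W_orth, T_orth


def inner_relations(
    T: np.ndarray, U: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Least-squares link between the two blocks' joint scores.

    Fits U ~ T B_T and T ~ U B_U without intercept (scores of centered data)
    and returns the coefficients, both residual matrices, and the two
    coefficients of determination.

    Returns
    -------
    B_T, B_U, H_UT, H_TU, r2_u_on_t, r2_t_on_u
        ``H_UT = U - T B_T`` and ``H_TU = T - U B_U``;
        ``r2_u_on_t = 1 - sum(H_UT^2)/sum(U^2)`` and symmetrically.
    """
    T = np.asarray(T, dtype=float)
    U = np.asarray(U, dtype=float)
    if T.shape != U.shape:
        raise ValueError(f"score shapes differ: {T.shape} vs {U.shape}")
    ss_t_cols = (T**2).sum(axis=0)
    ss_u_cols = (U**2).sum(axis=0)
    if np.any(ss_t_cols == 0) or np.any(ss_u_cols == 0):
        raise DegenerateScoresError("a score column has zero variance")
    B_T = np.linalg.pinv(T, rcond=PINV_RCOND) @ U
    B_U = np.linalg.pinv(U, rcond=PINV_RCOND) @ T
    H_UT = U - T @ B_T
    H_TU = T - U @ B_U
    r2_u_on_t = float(1.0 - (H_UT**2).sum() / (U**2).sum())
    r2_t_on_u = float(1.0 - (H_TU**2).sum() / (T**2).sum())
    return B_T, B_U, H_UT, H_TU, max(r2_u_on_t, 0.0), max(r2_t_on_u, 0.0)


def _regress_loadings(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Least-squares loadings P = block'scores (scores'scores)^-1."""
    G = scores.T @ scores
    return block.T @ scores @ np.linalg.pinv(G, rcond=PINV_RCOND)


@dataclass
class O2PLSModel:
    """All fitted quantities of an O2PLS decomposition.

    Joint loadings ``W`` (p x a), ``C`` (q x a) and scores ``T``, ``U``
    (N x a); orthogonal loadings ``W_Yorth``/``P_Yorth`` (p x n_x),
    ``C_Xorth``/``P_Xorth`` (q x n_y) with scores ``T_Yorth``, ``U_Xorth``;
    inner-relation coefficients ``B_T``, ``B_U`` (a x a) with residuals
    ``H_UT``, ``H_TU``; block residuals ``E``, ``F``.

    ``W``, ``C``, ``W_Yorth``, ``C_Xorth`` have orthonormal columns; the
    reconstruction X = T W' + T_Yorth P_Yorth' + E holds exactly by
    construction (symmetrically for Y).
    """

    a: int
    n_x: int
    n_y: int
    W: np.ndarray
    C: np.ndarray
    T: np.ndarray
    U: np.ndarray
    W_Yorth: np.ndarray
    P_Yorth: np.ndarray
    T_Yorth: np.ndarray
    C_Xorth: np.ndarray
    P_Xorth: np.ndarray
    U_Xorth: np.ndarray
    B_T: np.ndarray
    B_U: np.ndarray
    E: np.ndarray
    F: np.ndarray
    H_UT: np.ndarray
    H_TU: np.ndarray
    singular_values: np.ndarray
    r2_u_on_t: float
    r2_t_on_u: float
    column_means_x: np.ndarray
    column_means_y: np.ndarray
    # provisional (pre-deflation) joint loadings, kept for diagnostics
    W_provisional: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    C_provisional: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    # norm of (E W_Yorth - X W_Yorth): gap between the residual-based
    # orthogonal scores used here and the data-based variant
    t_yorth_gap: float = 0.0
    u_xorth_gap: float = 0.0

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.C.shape[0]


def fit_o2pls(
    data: PairedData,
    a: int,
    n_x: int,
    n_y: int,
    provisional_components: int | None = None,
) -> O2PLSModel:
    """Fit the O2PLS decomposition at fixed component numbers.

    Parameters
    ----------
    data
        Centered :class:`PairedData`.  Visibly uncentered blocks are refused
        rather than silently centered.
    a
        Number of joint components, 1 <= a <= min(p, q).
    n_x, n_y
        Numbers of orthogonal components in X and Y (0 allowed); bounded by
        n_x <= p - a and n_y <= q - a, and by the rank of the
        residual-score cross-product (the number of provisional joint
        components) — :class:`InsufficientRankError` is raised beyond it.
    provisional_components
        Number of provisional joint components used before orthogonal
        extraction; defaults to ``a``.  Since at most this many orthogonal
        components per block can be extracted, set it to
        ``max(a, n_x, n_y)`` to fit more block-specific than shared
        components.  Note that widening it makes the in-sample inner-R²
        criterion prone to absorbing noise (see :mod:`o2pls.selection`).

    Notes
    -----
    With ``n_x = n_y = 0`` the fit reduces to two-block PLS: a single SVD of
    X'Y.  Joint loadings are re-estimated by a second SVD after both
    orthogonal deflations, so the final joint part is corrected for the
    orthogonal variation.
    """
    X = np.asarray(data.X, dtype=float)
    Y = np.asarray(data.Y, dtype=float)
    N, p = X.shape
    q = Y.shape[1]
    for block, name in ((X, "X"), (Y, "Y")):
        scale = max(1.0, float(np.abs(block).max()))
        if np.abs(block.mean(axis=0)).max() > 1e-8 * scale:
            raise NotCenteredError(
                f"{name} is not column-mean centered; center before fitting"
            )
    if not 1 <= a <= min(p, q):
        raise InvalidComponentCountError(f"a={a} outside [1, {min(p, q)}]")
    if not 0 <= n_x <= p - a:
        raise InvalidComponentCountError(f"n_x={n_x} outside [0, p-a={p - a}]")
    if not 0 <= n_y <= q - a:
        raise InvalidComponentCountError(f"n_y={n_y} outside [0, q-a={q - a}]")

    # (1) provisional joint part.  rank(E0'T0) is capped by the number of
    # provisional components, so by default at most `a` orthogonal
    # components per block are extractable; `provisional_components` widens
    # the provisional subspace when more block-specific than shared axes
    # are wanted (e.g. one joint metabolite-transcript axis but eight
    # transcript-only axes).
    a_prov = a if provisional_components is None else provisional_components
    if a_prov < a or a_prov > min(p, q):
        raise InvalidComponentCountError(
            f"provisional_components={a_prov} outside [a={a}, min(p, q)={min(p, q)}]"
        )
    W0, C0, _ = joint_svd(X.T @ Y, a_prov)
    T0 = X @ W0
    U0 = Y @ C0

    Xd = X
    Yd = Y
    # (2) orthogonal part of X: overlap of the X-residual with T
    if n_x > 0:
        E0 = X - T0 @ W0.T
        W_Yorth, T_Yorth = extract_orthogonal(E0, T0, n_x)
        P_Yorth = _regress_loadings(X, T_Yorth)
        Xd = X - T_Yorth @ P_Yorth.T
        t_yorth_gap = float(np.linalg.norm(T_Yorth - X @ W_Yorth))
    else:
        W_Yorth = np.zeros((p, 0))
        P_Yorth = np.zeros((p, 0))
        T_Yorth = np.zeros((N, 0))
        t_yorth_gap = 0.0
    # (3) symmetric step on Y
    if n_y > 0:
        F0 = Y - U0 @ C0.T
        C_Xorth, U_Xorth = extract_orthogonal(F0, U0, n_y)
        P_Xorth = _regress_loadings(Y, U_Xorth)
        Yd = Y - U_Xorth @ P_Xorth.T
        u_xorth_gap = float(np.linalg.norm(U_Xorth - Y @ C_Xorth))
    else:
        C_Xorth = np.zeros((q, 0))
        P_Xorth = np.zeros((q, 0))
        U_Xorth = np.zeros((N, 0))
        u_xorth_gap = 0.0

    # (4) final joint part on the deflated cross-product
    W, C, d = joint_svd(Xd.T @ Yd, a)
    T = Xd @ W
    U = Yd @ C

    # (5) inner relations, (6) residuals
    B_T, B_U, H_UT, H_TU, r2_u_on_t, r2_t_on_u = inner_relations(T, U)
    E = Xd - T @ W.T
    F = Yd - U @ C.T

    means_x = (
        data.column_means_x if data.column_means_x is not None else np.zeros(p)
    )
    means_y = (
        data.column_means_y if data.column_means_y is not None else np.zeros(q)
    )
    return O2PLSModel(
        a=a,
        n_x=n_x,
        n_y=n_y,
        W=W,
        C=C,
        T=T,
        U=U,
        W_Yorth=W_Yorth,
        P_Yorth=P_Yorth,
        T_Yorth=T_Yorth,
        C_Xorth=C_Xorth,
        P_Xorth=P_Xorth,
        U_Xorth=U_Xorth,
        B_T=B_T,
        B_U=B_U,
        E=E,
        F=F,
        H_UT=H_UT,
        H_TU=H_TU,
        singular_values=d,
        r2_u_on_t=r2_u_on_t,
        r2_t_on_u=r2_t_on_u,
        column_means_x=np.asarray(means_x, dtype=float),
        column_means_y=np.asarray(means_y, dtype=float),
        W_provisional=W0,
        C_provisional=C0,
        t_yorth_gap=t_yorth_gap,
        u_xorth_gap=u_xorth_gap,
    )


def predict(
    model: O2PLSModel,
    new_block: np.ndarray,
    direction: str,
    means: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Predict one block from the other through the joint scores.

    ``x_to_y`` centers the new block, removes its orthogonal variation with
    the fitted filter (project on W_Yorth, subtract the P_Yorth
    reconstruction), projects onto the joint loadings W, pushes the scores
    through the inner regression B_T and maps back through C', then adds
    the Y means: (X_corr) W B_T C' + means_y.  Filtering the new samples is
    what makes the orthogonal part "not contribute to prediction" — without
    it, block-specific variation leaks into the joint scores wherever
    W'P_Yorth is nonzero.  ``y_to_x`` is symmetric via C_Xorth/P_Xorth, C,
    B_U and W'.

    Parameters
    ----------
    means
        Optional (source_means, target_means) override; by default the
        column means stored on the model at fit time are used.
    """
    new_block = np.atleast_2d(np.asarray(new_block, dtype=float))
    if direction == "x_to_y":
        src_means, tgt_means = (
            means if means is not None else (model.column_means_x, model.column_means_y)
        )
        if new_block.shape[1] != model.p:
            raise ValueError(
                f"expected {model.p} X-variables, got {new_block.shape[1]}"
            )
        Xc = new_block - src_means
        if model.n_x > 0:
            Xc = Xc - (Xc @ model.W_Yorth) @ model.P_Yorth.T
        return Xc @ model.W @ model.B_T @ model.C.T + tgt_means
    if direction == "y_to_x":
        src_means, tgt_means = (
            means if means is not None else (model.column_means_y, model.column_means_x)
        )
        if new_block.shape[1] != model.q:
            raise ValueError(
                f"expected {model.q} Y-variables, got {new_block.shape[1]}"
            )
        Yc = new_block - src_means
        if model.n_y > 0:
            Yc = Yc - (Yc @ model.C_Xorth) @ model.P_Xorth.T
        return Yc @ model.C @ model.B_U @ model.W.T + tgt_means
    raise ValueError(f"unknown direction {direction!r}; use 'x_to_y' or 'y_to_x'")
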