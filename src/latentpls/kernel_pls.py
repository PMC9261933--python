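"""Multivariate partial least squares by the cross-product ("kernel") algorithm.

PLS extracts latent components that maximize covariance between a
predictor block X (n x p) and a multivariate response block U (n x m),
both column-standardized. The model is

    X = T P' + E,    U = T Q' + F,

with scores T = X R, weights W, rotations R, loadings P (p x l) and
Q (m x l), and implied regression coefficients B = R Q' for predicting U
from X. The kernel form of the algorithm works from the cross-product
matrices X'U (and optionally X'X) alone, deflating only X'U between
components; it reproduces classical NIPALS PLS2 exactly, component by
component, and at the full number of components reproduces ordinary least
squares.

A classical NIPALS implementation (`nipals_pls`) is provided purely as an
independent oracle for testing, and `continuum_direction` implements the
Stone-Brooks continuum-regression family whose alpha = 0, 1/2, 1 members
are the OLS, first-PLS and first-principal-component directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """Fitted PLS decomposition.

    Attributes
    ----------
    weights : (p, l) ndarray
        Unit-norm weight vectors w_b computed from the deflated cross-product.
    rotations : (p, l) ndarray
        Rotations r_b with T = X @ rotations on the *undeflated* X.
    x_loadings : (p, l) ndarray
        Loadings p_b = X't_b / (t_b't_b).
    u_loadings : (m, l) ndarray
        Response loadings q_b.
    scores : (n, l) ndarray or None
        Component scores t_b = X r_b (None for the cross-product-only fit).
    score_norms : (l,) ndarray
        t_b' t_b per component.
    coefficients : (p, m) ndarray
        B = R Q', regression coefficients of U on X on the standardized scale.
    """

    n_components: int
    weights: np.ndarray
    rotations: np.ndarray
    x_loadings: np.ndarray
    u_loadings: np.ndarray
    scores: np.ndarray | None
    score_norms: np.ndarray
    coefficients: np.ndarray


def dominant_eigenvector(S: np.ndarray, sym_tol: float = 1e-10) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of a symmetric PSD matrix.

    The sign is fixed so the largest-magnitude entry is positive (first such
    entry on ties); a (near-)degenerate top eigenvalue is logged, since the
    returned vector is then only deterministic, not canonical.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("expected a square matrix")
    scale = max(1.0, np.abs(S).max())
    if np.abs(S - S.T).max() > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    evals, evecs = linalg.eigh(S)
    v = evecs[:, -1]
    if S.shape[0] > 1 and evals[-1] - evals[-2] <= 1e-10 * max(1.0, evals[-1]):
        logger.warning("dominant eigenvalue is degenerate (gap %.3g); "
                       "returning deterministic tie-broken eigenvector",
                       evals[-1] - evals[-2])
    return _fix_sign(v)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip v so its largest-|entry| (first on ties) is positive."""
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def fit_kernel_pls(X_std: np.ndarray, U_std: np.ndarray, l: int,
                   compute_scores: bool = True) -> PLSModel:
    """Fit l-component multivariate PLS from cross-products.

    Per component b: q_b is the dominant eigenvector of (X'U)_b'(X'U)_b;
    w_b = (X'U)_b q_b scaled to unit norm and sign-fixed; the rotation
    r_b = w_b - sum_{a<b} (p_a'w_b) r_a maps undeflated X to scores
    t_b = X r_b; loadings p_b = X't_b/(t_b't_b), q_b' = r_b'(X'U)_b/(t_b't_b);
    then (X'U)_{b+1} = (X'U)_b - p_b q_b' (t_b't_b). Finally B = R Q'.

    With ``compute_scores=False`` the score vectors are never formed:
    t_b't_b = r_b'(X'X)r_b and p_b = (X'X)r_b/(t_b't_b), so the whole fit
    runs on X'X and X'U. Both paths return identical coefficients; the
    cross-product-only path just leaves ``scores`` as None.
    """
    X = np.asarray(X_std, dtype=float)
    U = np.asarray(U_std, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    n, p = X.shape
    if U.shape[0] != n:
        raise ValueError("X and U must have the same number of rows")
    m = U.shape[1]
    if n < 3:
        raise ValueError("need at least 3 rows")
    rank = np.linalg.matrix_rank(X)
    if not 1 <= l <= rank:
        raise ValueError(f"n_components must be in [1, rank(X)={rank}], got {l}")

    A = X.T @ U  # deflated cross-product (X'U)_b
    XtX = None if compute_scores else X.T @ X

    W = np.empty((p, l))
    R = np.empty((p, l))
    P = np.empty((p, l))
    Q = np.empty((m, l))
    T = np.empty((n, l)) if compute_scores else None
    tt = np.empty(l)

    for b in range(l):
        if np.linalg.norm(A) < 1e-12:
            raise ValueError(
                f"no remaining covariance between X and U at component {b + 1}"
            )
        if m == 1:
            w = A[:, 0].copy()
        else:
            q = dominant_eigenvector(A.T @ A)
            w = A @ q
        w /= np.linalg.norm(w)
        w = _fix_sign(w)
        r = w - R[:, :b] @ (P[:, :b].T @ w)
        if compute_scores:
            t = X @ r
            tt[b] = t @ t
            pvec = X.T @ t / tt[b]
            T[:, b] = t
        else:
            Sr = XtX @ r
            tt[b] = r @ Sr
            pvec = Sr / tt[b]
        qvec = A.T @ r / tt[b]
        A = A - np.outer(pvec, qvec) * tt[b]
        W[:, b], R[:, b], P[:, b], Q[:, b] = w, r, pvec, qvec

    B = R @ Q.T
    return PLSModel(n_components=l, weights=W, rotations=R, x_loadings=P,
                    u_loadings=Q, scores=T, score_norms=tt, coefficients=B)


def pls_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Component scores X_new @ R for rows standardized with the training map."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.rotations.shape[0]:
        raise ValueError(
            f"expected {model.rotations.shape[0]} columns, got {X_new.shape[1]}"
        )
    return X_new @ model.rotations


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses X_new @ B on the standardized scale."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"expected {model.coefficients.shape[0]} columns, got {X_new.shape[1]}"
        )
    return X_new @ model.coefficients


def nipals_pls(X_std: np.ndarray, U_std: np.ndarray, l: int,
               max_iter: int = 500, tol: float = 1e-12) -> PLSModel:
    """Classical NIPALS PLS2 with explicit X (and U) deflation.

    Independent test oracle for `fit_kernel_pls`: iterates in score space,
    deflating the data matrices between components. Same sign convention
    (w_b oriented so its largest-|entry| is positive). Not used by the
    estimation pipeline.
    """
    X = np.array(X_std, dtype=float)
    U = np.array(U_std, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    n, p = X.shape
    m = U.shape[1]
    rank = np.linalg.matrix_rank(X)
    if not 1 <= l <= rank:
        raise ValueError(f"n_components must be in [1, rank(X)={rank}], got {l}")

    W = np.empty((p, l))
    P = np.empty((p, l))
    Q = np.empty((m, l))
    T = np.empty((n, l))
    tt = np.empty(l)

    for b in range(l):
        # start from the response column with the largest sum of squares
        u = U[:, int(np.argmax((U ** 2).sum(axis=0)))].copy()
        w_old = None
        for it in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = U.T @ t / (t @ t)
            if m == 1:
                break
            u = U @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            raise RuntimeError(f"NIPALS did not converge for component {b + 1}")
        if w[int(np.argmax(np.abs(w)))] < 0:  # align with kernel sign rule
            w, t, q = -w, -t, -q
        tt[b] = t @ t
        pvec = X.T @ t / tt[b]
        qvec = U.T @ t / tt[b]
        X -= np.outer(t, pvec)
        U -= np.outer(t, qvec)
        W[:, b], P[:, b], Q[:, b], T[:, b] = w, pvec, qvec, t

    R = W @ np.linalg.inv(P.T @ W)
    B = R @ Q.T
    return PLSModel(n_components=l, weights=W, rotations=R, x_loadings=P,
                    u_loadings=Q, scores=T, score_norms=tt, coefficients=B)


@dataclass
class ContinuumDirection:
    alpha: float
    direction: np.ndarray


def continuum_objective(X_std: np.ndarray, y: np.ndarray, beta: np.ndarray,
                        alpha: float, form: str = "standard") -> float:
    """Evaluate the continuum-regression objective at a direction beta.

    ``form='standard'`` is the criterion whose alpha = 0, 1/2, 1 maximizers
    are the OLS, PLS and PCR directions:

        Cov(y, X beta)^2 * Var(X beta)^(alpha/(1-alpha) - 1).

    ``form='variance_first'`` swaps the roles of the variance and covariance
    factors; it is exposed for inspection but does not reproduce the
    OLS/PLS/PCR anchor correspondence and is not used by
    `continuum_direction`.
    """
    z = np.asarray(X_std, float) @ np.asarray(beta, float)
    y = np.asarray(y, float)
    n = y.size
    cov = (y - y.mean()) @ (z - z.mean()) / (n - 1)
    var = z.var(ddof=1)
    if alpha >= 1.0:
        return var if form == "standard" else cov
    expo = alpha / (1.0 - alpha) - 1.0
    if form == "standard":
        return cov ** 2 * var ** expo
    if form == "variance_first":
        return var ** 2 * cov ** expo
    raise ValueError(f"unknown objective form '{form}'")


def continuum_direction(X_std: np.ndarray, y: np.ndarray, alpha: float,
                        method: str = "auto") -> ContinuumDirection:
    """Direction maximizing the continuum-regression criterion over unit beta.

    Closed forms at the anchors: alpha=0 gives the OLS direction
    (X'X)^{-1}X'y; alpha=1/2 gives the first PLS weight, proportional to
    X'y; alpha=1 gives the dominant eigenvector of X'X. For other alpha the
    maximizer lies on the one-parameter ridge family
    beta(delta) ~ (X'X - delta I)^{-1} X'y evaluated in the eigenbasis of
    X'X, and a scalar search over delta is used: delta in (-inf, 0] spans
    the OLS-to-PLS arc (alpha < 1/2) and delta > lambda_max spans the
    PLS-to-PCR arc (alpha > 1/2).
    """
    X = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if p > n:
        raise ValueError("continuum_direction requires p <= n")
    S = X.T @ X
    s = X.T @ (y - y.mean())

    if method not in ("auto", "closed", "numeric"):
        raise ValueError(f"unknown method '{method}'")
    use_closed = method != "numeric" and alpha in (0.0, 0.5, 1.0)
    if use_closed:
        if alpha == 0.0:
            beta = _solve_ols(S, s)
        elif alpha == 0.5:
            beta = s.copy()
        else:
            beta = dominant_eigenvector(S)
        return ContinuumDirection(alpha=alpha, direction=_unit(beta))
    if method == "closed":
        raise ValueError("closed form only available at alpha in {0, 1/2, 1}")

    evals, V = linalg.eigh(S)
    c = V.T @ s
    lam_max = evals[-1]

    def beta_of_delta(delta: float) -> np.ndarray:
        return V @ (c / (evals - delta))

    def neg_obj(u: float) -> float:
        if alpha <= 0.5:
            delta = -lam_max * np.expm1(u)  # u in [0, 35]: delta from 0 to -inf
        else:
            delta = lam_max * (1.0 + np.exp(-u))  # u large: delta -> lam_max+
        beta = _unit(beta_of_delta(delta))
        val = continuum_objective(X, y, beta, alpha)
        return -val

    res = optimize.minimize_scalar(neg_obj, bounds=(0.0, 35.0) if alpha <= 0.5
                                   else (-5.0, 35.0), method="bounded",
                                   options={"xatol": 1e-10})
    u = res.x
    # check the boundaries too: the optimum may sit at an anchor
    candidates = [u, 0.0 if alpha <= 0.5 else -5.0, 35.0]
    u_best = min(candidates, key=neg_obj)
    if alpha <= 0.5:
        beta = beta_of_delta(-lam_max * np.expm1(u_best))
    else:
        beta = beta_of_delta(lam_max * (1.0 + np.exp(-u_best)))
    return ContinuumDirection(alpha=alpha, direction=_unit(beta))


def _solve_ols(S: np.ndarray, s: np.ndarray) -> np.ndarray:
    try:
        cho = linalg.cho_factor(S)
    except linalg.LinAlgError as exc:
        raise ValueError("X'X is singular; the OLS direction is undefined") from exc
    if np.linalg.cond(S) > 1e12:
        raise ValueError("X'X is singular; the OLS direction is undefined")
    return linalg.cho_solve(cho, s)


def _unit(v: np.ndarray) -> np.ndarray:
    return _fix_sign(v / np.linalg.norm(v))


def dump_model_tsv(model: PLSModel, out_dir) -> None:
    """Write W/R/P/Q/T/B as TSV files into out_dir for inspection."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parts = {"weights": model.weights, "rotations": model.rotations,
             "x_loadings": model.x_loadings, "u_loadings": model.u_loadings,
             "coefficients": model.coefficients}
    if model.scores is not None:
        parts["scores"] = model.scores
    for name, arr in parts.items():
        np.savetxt(out / f"{name}.tsv", arr, delimiter="\t")
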