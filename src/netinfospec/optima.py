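"""Optimal background states and reference inputs by Rayleigh-quotient
optimization.

tr(I_u) is a generalized Rayleigh quotient — a ratio of two quadratic
forms in x_ref. Whitening by the Cholesky factor L of the denominator
matrix (x* = L^T x_ref) turns it into an ordinary Rayleigh quotient of

    S = L^{-1} Gamma B B^T Gamma^T L^{-T},       L L^T = Sigma_x,

so the optimum over background states is the principal eigenvector of S
back-transformed through L^{-T} — the Fisher linear discriminant of the
stimulus-induced state distributions. Restricting the background to ones
reachable by a constant input (x_ref = Gamma B u_ref) yields the analogous
m-dimensional problem with

    S_u = L^{-1} (G^T G)(G^T G) L^{-T},   G = Gamma B,   L L^T = G^T Sigma_x G.

The eigenvalue spectrum of S_u is the network's information spectrum: the
i-th eigenvalue is the readout information attained when u_ref is the i-th
whitened input direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .fisherinfo import DEFAULT_T
from .lindyn import gamma_matrix, steady_covariance
from .netgen import LinearNetwork

__all__ = [
    "DiscriminantProblem",
    "optimal_xref",
    "optimal_uref",
    "information_spectrum",
    "alignment_cosine",
    "sign_fix",
    "rayleigh_refine",
    "CholeskyError",
]

log = logging.getLogger(__name__)


class CholeskyError(np.linalg.LinAlgError):
    """A required denominator matrix is not positive-definite."""


def sign_fix(v: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign: largest-magnitude component made positive."""
    v = np.asarray(v, dtype=float)
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v.copy()


def _chol(M: np.ndarray, name: str) -> np.ndarray:
    """Lower Cholesky factor, with a single jittered retry (logged)."""
    M = (M + M.T) / 2.0
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * np.trace(M)
        log.warning("Cholesky of %s failed; retrying with jitter %.3e", name, jitter)
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise CholeskyError(f"{name} is not positive-definite") from exc


def _sym_eig(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition after numerical symmetrization; PSD asserted."""
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w[-1] > 0 and w[0] < -1e-10 * w[-1]:
        raise np.linalg.LinAlgError(
            f"matrix expected PSD has eigenvalue {w[0]:.3e} (max {w[-1]:.3e})"
        )
    return w, V


@dataclass(frozen=True)
class DiscriminantProblem:
    """A solved whitened Rayleigh-quotient problem.

    ``space`` is ``"state"`` (optimize x_ref over R^n) or ``"input"``
    (optimize u_ref over R^m). ``S`` is the whitened matrix whose spectrum
    bounds tr(I_u); ``L`` the Cholesky factor of the denominator form;
    ``v_star`` the principal whitened eigenvector; ``v_opt`` its unit-norm
    back-transformation L^{-T} v_star — the optimal x_ref or u_ref.
    ``degenerate`` flags a (near-)multiple top eigenvalue.
    """

    space: str
    S: np.ndarray
    L: np.ndarray
    eigenvalues: np.ndarray
    lambda_max: float
    lambda_min: float
    v_star: np.ndarray
    v_opt: np.ndarray
    degenerate: bool


def _solve(numerator: np.ndarray, denominator: np.ndarray, space: str,
           denom_name: str) -> DiscriminantProblem:
    L = _chol(denominator, denom_name)
    # S = L^{-1} N L^{-T} via two triangular solves
    tmp = scipy.linalg.solve_triangular(L, numerator, lower=True)
    S = scipy.linalg.solve_triangular(L, tmp.T, lower=True).T
    w, V = _sym_eig(S)
    v_star = sign_fix(V[:, -1])
    v_opt = scipy.linalg.solve_triangular(L.T, v_star, lower=False)
    v_opt = sign_fix(v_opt / np.linalg.norm(v_opt))
    degenerate = w.size > 1 and (w[-1] - w[-2]) <= 1e-10 * max(w[-1], 1e-300)
    return DiscriminantProblem(
        space=space, S=(S + S.T) / 2.0, L=L, eigenvalues=w,
        lambda_max=float(w[-1]), lambda_min=float(w[0]),
        v_star=v_star, v_opt=v_opt, degenerate=degenerate,
    )


def optimal_xref(
    net: LinearNetwork,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> tuple[np.ndarray, float, DiscriminantProblem]:
    """Background state maximizing tr(I_u) over all of R^n.

    Returns ``(x_ref_opt, lambda_max, problem)`` with ``x_ref_opt`` unit-norm
    (the trace is scale-invariant; normalization makes realizations
    comparable) and ``lambda_max = fisher_trace(net, x_ref_opt, t)``, the
    largest eigenvalue of the whitened matrix S.
    """
    G = gamma_matrix(net, t) if gamma is None else gamma
    Sx = steady_covariance(net) if sigma_x is None else sigma_x
    GB = G @ net.B
    prob = _solve(GB @ GB.T, Sx, "state", "Sigma_x")
    return prob.v_opt, prob.lambda_max, prob


def optimal_uref(
    net: LinearNetwork,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> tuple[np.ndarray, float, DiscriminantProblem]:
    """Constant input whose induced background x~ = Gamma B u_ref maximizes
    tr(I_u) among all input-reachable backgrounds.

    Returns ``(u_ref_opt, lambda_max, problem)`` with ``u_ref_opt`` unit-norm
    ("unitary") and ``lambda_max`` the largest eigenvalue of S_u. Requires
    B^T Gamma^T Sigma_x Gamma B positive-definite, which holds whenever
    Sigma_x is PD and Gamma B has full column rank (controllable, stable
    pair).
    """
    G = gamma_matrix(net, t) if gamma is None else gamma
    Sx = steady_covariance(net) if sigma_x is None else sigma_x
    GB = G @ net.B
    GtG = GB.T @ GB
    denom = GB.T @ Sx @ GB
    try:
        prob = _solve(GtG @ GtG, denom, "input", "B^T Gamma^T Sigma_x Gamma B")
    except CholeskyError as exc:
        raise CholeskyError(
            "B^T Gamma^T Sigma_x Gamma B is rank-deficient: the pair (A, B) "
            "has lost controllability or conditioning"
        ) from exc
    return prob.v_opt, prob.lambda_max, prob


def information_spectrum(
    net: LinearNetwork,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> np.ndarray:
    """All m eigenvalues of S_u, ascending — the information spectrum."""
    _, _, prob = optimal_uref(net, t, gamma=gamma, sigma_x=sigma_x)
    return prob.eigenvalues


def alignment_cosine(
    v1: np.ndarray, v2: np.ndarray, indices: np.ndarray | None = None
) -> float:
    """|cos| of the angle between (sub)vectors: |<v1_I, v2_I>|/(|v1_I||v2_I|).

    The absolute value is taken because eigenvector-valued arguments are
    defined only up to sign. ``indices`` restricts both vectors to a node
    subset (e.g. actuated nodes only).
    """
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("v1, v2 must have equal length")
    if indices is not None:
        idx = np.asarray(indices)
        a, b = a[idx], b[idx]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("alignment undefined for a zero (sub)vector")
    return float(min(abs(a @ b) / (na * nb), 1.0))


def rayleigh_refine(
    S: np.ndarray, v0: np.ndarray, *, iters: int = 500, tol: float = 1e-14
) -> tuple[np.ndarray, float]:
    """Power-iteration refinement of an approximate principal eigenvector of
    a symmetric PSD matrix; returns (unit vector, Rayleigh quotient).

    Used as a local-ascent cross-check that random search plus refinement
    reaches lambda_max.
    """
    S = (S + S.T) / 2.0
    v = np.asarray(v0, dtype=float).ravel()
    v = v / np.linalg.norm(v)
    lam = float(v @ S @ v)
    for _ in range(iters):
        w = S @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:
            break
        v_new = w / nw
        lam_new = float(v_new @ S @ v_new)
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1.0):
            return v_new, lam_new
        v, lam = v_new, lam_new
    return v, lam
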