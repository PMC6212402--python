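"""Deterministic and stochastic response objects of the linear system.

For the stable system dx/dt = A x + B u + w with constant input u, the
state at time t is Gaussian with mean Gamma(t) B u, where

    Gamma(t) = int_0^t exp(A (t - tau)) d tau

is the constant-input propagator, and covariance taken at steady state:
the unique solution Sigma_x of the Lyapunov equation

    A Sigma_x + Sigma_x A^T + Sigma_w = 0.

The controllability gramian W(t) = int_0^t exp(A s) B B^T exp(A^T s) ds is
the same integral with B B^T in place of Sigma_w; W(inf) solves the
Lyapunov equation with B B^T, so when Sigma_w = B B^T the infinite-time
gramian and the steady-state covariance coincide exactly.

Finite-time integrals are computed without quadrature: for stable A via
the decay identity X(t) = X(inf) - e^{At} X(inf) e^{A^T t} (only decaying
exponentials appear), with Van Loan's augmented-matrix-exponential block
identity as the general fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse

from .netgen import LinearNetwork

__all__ = [
    "gamma_matrix",
    "state_mean",
    "steady_covariance",
    "finite_time_covariance",
    "gramian",
    "PropagatorSet",
]

_COND_LIMIT = 1e8


def _as_A(net_or_A: LinearNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net_or_A, LinearNetwork):
        return net_or_A.A
    return np.atleast_2d(np.asarray(net_or_A, dtype=float))


def gamma_matrix(net: LinearNetwork | np.ndarray, t: float) -> np.ndarray:
    """Constant-input propagator Gamma(t) = int_0^t exp(A(t-tau)) dtau.

    Computed in closed form as A^{-1} (exp(A t) - I) when A is
    well-conditioned; otherwise via the top-right block of
    exp([[A, I], [0, 0]] t), which needs no inversion. Gamma(0) = 0;
    Gamma(t) -> -A^{-1} as t -> inf for stable A.
    """
    A = _as_A(net)
    if t < 0:
        raise ValueError("t must be nonnegative")
    n = A.shape[0]
    if t == 0:
        return np.zeros_like(A)
    if np.linalg.cond(A) < _COND_LIMIT:
        G = np.linalg.solve(A, scipy.linalg.expm(A * t) - np.eye(n))
    else:
        M = np.zeros((2 * n, 2 * n))
        M[:n, :n] = A
        M[:n, n:] = np.eye(n)
        G = scipy.linalg.expm(M * t)[:n, n:]
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite entries in Gamma(t)")
    return G


def state_mean(net: LinearNetwork, u: np.ndarray, t: float) -> np.ndarray:
    """Mean state E[x(t)] = Gamma(t) B u under constant input u."""
    u = np.asarray(u, dtype=float).ravel()
    if u.size != net.m:
        raise ValueError(f"u has length {u.size}, expected m={net.m}")
    return gamma_matrix(net, t) @ net.B @ u


def _lyapunov(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve A X + X A^T + Q = 0 for stable A; symmetrized."""
    if np.linalg.eigvals(A).real.max() >= 0:
        raise ValueError("A must be Hurwitz-stable for a steady-state solution")
    X = scipy.linalg.solve_continuous_lyapunov(A, -Q)
    return (X + X.T) / 2.0


def steady_covariance(net: LinearNetwork) -> np.ndarray:
    """Steady-state state covariance: the solution of
    A Sigma + Sigma A^T + Sigma_w = 0 (symmetric, PD for PD Sigma_w)."""
    return _lyapunov(net.A, net.Sigma_w)


def _vanloan_integral(A: np.ndarray, Q: np.ndarray, t: float) -> np.ndarray:
    """int_0^t exp(A s) Q exp(A^T s) ds via the block identity
    expm([[-A, Q], [0, A^T]] t) = [[.., F12], [0, F22]], integral = F22^T F12.

    Accurate for moderate |eig(A)| * t only: the augmented matrix contains
    growing modes exp(+|eig| t). Used for small steps and as the fallback
    when A is not stable; stable systems use :func:`_decay_integral`.
    """
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = Q
    M[n:, n:] = A.T
    F = scipy.linalg.expm(M * t)
    X = F[n:, n:].T @ F[:n, n:]
    return (X + X.T) / 2.0


def _decay_integral(A: np.ndarray, Q: np.ndarray, t: float) -> np.ndarray:
    """int_0^t exp(A s) Q exp(A^T s) ds for STABLE A, via the identity
    X(t) = X(inf) - exp(A t) X(inf) exp(A^T t): only decaying exponentials
    appear, so the computation stays accurate for any t."""
    Xinf = _lyapunov(A, Q)
    E = scipy.linalg.expm(A * t)
    X = Xinf - E @ Xinf @ E.T
    return (X + X.T) / 2.0


def _finite_integral(A: np.ndarray, Q: np.ndarray, t: float) -> np.ndarray:
    if np.linalg.eigvals(A).real.max() < 0:
        return _decay_integral(A, Q, t)
    return _vanloan_integral(A, Q, t)


def finite_time_covariance(net: LinearNetwork, t: float) -> np.ndarray:
    """Covariance of x(t) started from a deterministic state:
    int_0^t exp(A s) Sigma_w exp(A^T s) ds.

    Provided for completeness; the analysis pipeline always uses the
    steady-state covariance (persistent noise excitation), see
    :func:`steady_covariance`.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return np.zeros_like(net.A)
    return _finite_integral(net.A, net.Sigma_w, t)


def gramian(net: LinearNetwork, t: float = np.inf) -> np.ndarray:
    """Controllability gramian W(t); ``t=np.inf`` gives the Lyapunov
    solution A W + W A^T + B B^T = 0."""
    BBt = net.B @ net.B.T
    if np.isinf(t):
        return _lyapunov(net.A, BBt)
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return np.zeros_like(net.A)
    return _finite_integral(net.A, BBt, t)


@dataclass(frozen=True)
class PropagatorSet:
    """Cache of the linear-system response objects at one evaluation time.

    Fields: the propagator ``Gamma`` = Gamma(t), steady-state covariance
    ``Sigma_x``, finite-time gramian ``W_t`` and infinite-time gramian
    ``W_inf``.
    """

    t: float
    Gamma: np.ndarray
    Sigma_x: np.ndarray
    W_t: np.ndarray
    W_inf: np.ndarray

    @classmethod
    def from_network(cls, net: LinearNetwork, t: float = 10.0) -> "PropagatorSet":
        return cls(
            t=float(t),
            Gamma=gamma_matrix(net, t),
            Sigma_x=steady_covariance(net),
            W_t=gramian(net, t),
            W_inf=gramian(net, np.inf),
        )

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("Gamma", "Sigma_x", "W_t", "W_inf"):
            scipy.io.mmwrite(d / f"{name}.mtx", scipy.sparse.coo_matrix(getattr(self, name)))
        (d / "propagators.json").write_text(json.dumps({"t": self.t}))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "PropagatorSet":
        d = Path(directory)
        mats = {
            name: np.asarray(scipy.io.mmread(d / f"{name}.mtx").todense())
            for name in ("Gamma", "Sigma_x", "W_t", "W_inf")
        }
        t = json.loads((d / "propagators.json").read_text())["t"]
        return cls(t=t, **mats)
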