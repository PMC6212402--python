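"""Fisher information of the inner-product readout.

The only observable is the scalar projection <x(t), x_ref> of the network
state onto a fixed background state x_ref. Since x(t) is Gaussian with mean
Gamma(t) B u and steady-state covariance Sigma_x, the readout has mean
x_ref^T Gamma B u and variance x_ref^T Sigma_x x_ref — the stimulus u
shifts the mean but cancels out of the variance. The Fisher information
matrix for u given the readout is therefore the rank-one outer product

    I_u = (B^T Gamma^T x_ref) (x_ref^T Gamma B) / (x_ref^T Sigma_x x_ref)

with trace

    tr(I_u) = x_ref^T Gamma B B^T Gamma^T x_ref / (x_ref^T Sigma_x x_ref),

a ratio of quadratic forms that is invariant to rescaling x_ref and
independent of u. tr(I_u) lower-bounds the precision (inverse variance)
achievable by any unbiased estimator of u from readout samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lindyn import gamma_matrix, steady_covariance
from .netgen import LinearNetwork

__all__ = [
    "inner_product_variance",
    "fisher_matrix",
    "fisher_trace",
    "readout",
    "FisherReadout",
    "DegenerateReadoutError",
]

DEFAULT_T = 10.0


class DegenerateReadoutError(ValueError):
    """x_ref lies (numerically) in the null space of the readout variance."""


def _check_xref(x_ref: np.ndarray) -> np.ndarray:
    x = np.asarray(x_ref, dtype=float).ravel()
    if x.size == 0 or not np.any(x):
        raise ValueError("x_ref must be a nonzero vector")
    return x


def inner_product_variance(x_ref: np.ndarray, Sigma_x: np.ndarray) -> float:
    """Variance of the readout <x, x_ref>: x_ref^T Sigma_x x_ref.

    Independent of the stimulus u (the mean-shift terms cancel exactly).
    """
    x = _check_xref(x_ref)
    Sigma_x = np.asarray(Sigma_x, dtype=float)
    v = float(x @ Sigma_x @ x)
    lam_max = float(np.linalg.eigvalsh((Sigma_x + Sigma_x.T) / 2.0).max())
    if v < 1e-14 * float(x @ x) * lam_max:
        raise DegenerateReadoutError(
            "readout variance vanishes numerically; Sigma_x is not "
            "positive-definite along x_ref"
        )
    return v


def _gamma_sigma(
    net: LinearNetwork,
    t: float,
    gamma: np.ndarray | None,
    sigma_x: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    if gamma is None:
        gamma = gamma_matrix(net, t)
    if sigma_x is None:
        sigma_x = steady_covariance(net)
    return gamma, sigma_x


def fisher_matrix(
    net: LinearNetwork,
    x_ref: np.ndarray,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> np.ndarray:
    """Fisher information matrix I_u (m x m, symmetric PSD, rank <= 1).

    ``gamma`` / ``sigma_x`` may be supplied to reuse precomputed
    propagators; they must match ``net`` and ``t``.
    """
    x = _check_xref(x_ref)
    G, S = _gamma_sigma(net, t, gamma, sigma_x)
    denom = inner_product_variance(x, S)
    v = net.B.T @ G.T @ x
    return np.outer(v, v) / denom


def fisher_trace(
    net: LinearNetwork,
    x_ref: np.ndarray,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> float:
    """tr(I_u) = ||B^T Gamma^T x_ref||^2 / (x_ref^T Sigma_x x_ref)."""
    x = _check_xref(x_ref)
    G, S = _gamma_sigma(net, t, gamma, sigma_x)
    denom = inner_product_variance(x, S)
    v = net.B.T @ G.T @ x
    return float(v @ v) / denom


@dataclass(frozen=True)
class FisherReadout:
    """A full (x_ref, t) evaluation: information matrix, trace, variance."""

    x_ref: np.ndarray
    t: float
    I_u: np.ndarray
    trace: float
    inner_var: float


def readout(
    net: LinearNetwork,
    x_ref: np.ndarray,
    t: float = DEFAULT_T,
    *,
    gamma: np.ndarray | None = None,
    sigma_x: np.ndarray | None = None,
) -> FisherReadout:
    """Evaluate the readout at one background state."""
    x = _check_xref(x_ref)
    G, S = _gamma_sigma(net, t, gamma, sigma_x)
    denom = inner_product_variance(x, S)
    v = net.B.T @ G.T @ x
    I_u = np.outer(v, v) / denom
    return FisherReadout(
        x_ref=x, t=float(t), I_u=I_u, trace=float(v @ v) / denom, inner_var=denom
    )
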