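"""Stochastic trajectory simulation of the noisy linear network.

Serves as the empirical oracle for the analytic results: endpoint
ensembles of dx = (A x + B u) dt + dW, with dW ~ N(0, Sigma_w dt), should
be distributed N(Gamma(t) B u, Sigma_x) once the noise process is at
steady state — which the experiments assume throughout (the network is
persistently noise-excited, and stimuli arrive punctately). The simulator
realizes that regime directly: paths start from the stationary zero-input
distribution (or from zero with a burn-in), then the constant stimulus is
switched on for the requested duration.

Two steppers are available: plain Euler–Maruyama (default, transparent,
weak order 1) and the exact Gaussian one-step sampler built from e^{A dt},
the dt-step propagator and the dt-step Lyapunov integral, which has no
discretization bias and serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .lindyn import _vanloan_integral, gamma_matrix, steady_covariance
from .netgen import LinearNetwork

__all__ = ["TrajectorySample", "simulate", "empirical_readout_variance"]


@dataclass(frozen=True)
class TrajectorySample:
    """Endpoint ensemble of simulated paths.

    ``endpoints`` holds one state vector per path, sampled at time
    ``horizon`` (measured from stimulus onset; any burn-in ran before it).
    """

    endpoints: np.ndarray  # (n_paths, n)
    u: np.ndarray
    dt: float
    horizon: float
    burn_in: float
    method: str
    seed: int

    @property
    def n_paths(self) -> int:
        return self.endpoints.shape[0]


def _euler_steps(
    x: np.ndarray,
    A: np.ndarray,
    drive: np.ndarray,
    Lw: np.ndarray,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    sqdt = np.sqrt(dt)
    for _ in range(n_steps):
        dw = rng.standard_normal(x.shape) @ Lw.T
        x = x + dt * (x @ A.T + drive) + sqdt * dw
    return x


def simulate(
    net: LinearNetwork,
    u: np.ndarray,
    *,
    dt: float = 1e-3,
    horizon: float = 10.0,
    burn_in: float | None = None,
    n_paths: int = 1000,
    seed: int = 0,
    method: str = "euler",
    init: str = "stationary",
) -> TrajectorySample:
    """Simulate ``n_paths`` independent trajectories and return endpoints.

    The zero-input phase (burn-in or stationary initialization) brings the
    noise process to steady state; the constant stimulus ``u`` then acts
    for ``horizon`` time units, so endpoints approximate
    N(Gamma(horizon) B u, Sigma_x).

    Parameters
    ----------
    init : {"stationary", "zero"}
        ``stationary`` draws x(0) ~ N(0, Sigma_x) exactly (default; no
        burn-in needed). ``zero`` starts at the origin and runs a
        zero-input burn-in of ``burn_in`` time units (default: ten times
        the slowest time constant 1/min|Re eig(A)|).
    method : {"euler", "exact"}
        Euler–Maruyama, or the exact Gaussian one-step discretization.
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.size != net.m:
        raise ValueError(f"u has length {u.size}, expected m={net.m}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    eigs = np.linalg.eigvals(net.A)
    rate = float(np.abs(eigs.real).max())
    if method == "euler" and dt * rate > 0.1:
        raise ValueError(
            f"dt={dt} too coarse for |Re eig(A)|_max={rate:.3g}: "
            f"dt * rate = {dt * rate:.3g} > 0.1; reduce dt below {0.1 / rate:.3g}"
        )
    rng = np.random.default_rng(seed)
    Sigma_x = steady_covariance(net)
    drive = net.B @ u

    if init == "stationary":
        Lx = np.linalg.cholesky(Sigma_x + 1e-14 * np.trace(Sigma_x) * np.eye(net.n))
        x = rng.standard_normal((n_paths, net.n)) @ Lx.T
        burn = 0.0
    elif init == "zero":
        slowest = 1.0 / float(np.abs(eigs.real).min())
        burn = 10.0 * slowest if burn_in is None else float(burn_in)
        x = np.zeros((n_paths, net.n))
    else:
        raise ValueError(f"unknown init {init!r}")

    n_burn = int(round(burn / dt))
    n_stim = int(round(horizon / dt))

    if method == "euler":
        Lw = np.linalg.cholesky(net.Sigma_w)
        if n_burn:
            x = _euler_steps(x, net.A, np.zeros(net.n), Lw, dt, n_burn, rng)
        x = _euler_steps(x, net.A, drive, Lw, dt, n_stim, rng)
    elif method == "exact":
        E = scipy.linalg.expm(net.A * dt)
        Q = _vanloan_integral(net.A, net.Sigma_w, dt)
        Lq = np.linalg.cholesky(Q + 1e-15 * np.trace(Q) * np.eye(net.n))
        step_mean = gamma_matrix(net, dt) @ drive
        for _ in range(n_burn):
            x = x @ E.T + rng.standard_normal((n_paths, net.n)) @ Lq.T
        for _ in range(n_stim):
            x = x @ E.T + step_mean + rng.standard_normal((n_paths, net.n)) @ Lq.T
    else:
        raise ValueError(f"unknown method {method!r}")

    return TrajectorySample(
        endpoints=x, u=u, dt=float(dt), horizon=float(horizon),
        burn_in=float(burn), method=method, seed=int(seed),
    )


def empirical_readout_variance(
    sample: TrajectorySample, x_ref: np.ndarray
) -> tuple[float, float]:
    """Sample variance of the readout <x_endpoint, x_ref> across paths.

    Returns ``(variance, standard_error)``; the standard error uses the
    Gaussian approximation var * sqrt(2 / (k - 1)).
    """
    x_ref = np.asarray(x_ref, dtype=float).ravel()
    k = sample.n_paths
    if k < 2:
        raise ValueError("need at least 2 paths to estimate a variance")
    y = sample.endpoints @ x_ref
    var = float(np.var(y, ddof=1))
    se = var * np.sqrt(2.0 / (k - 1))
    return var, se
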