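"""Seeded generation of stable linear dynamical networks.

The systems studied here are noisy linear networks

    dx/dt = A x + B u + w(t),      w ~ N(0, Sigma_w)

where ``A`` couples the nodes (symmetric off-diagonal adjacency plus a
stabilizing negative diagonal), ``B`` routes an m-dimensional constant
stimulus onto a subset of "driver" nodes, and ``w`` is white state noise.
Two topology families are provided: Barabási–Albert scale-free graphs with
binary edge weights, and Erdős–Rényi graphs with small positive weights.

Stability is guaranteed by strict diagonal dominance: each diagonal entry is
set to minus the row sum of the off-diagonal entries minus a margin
``delta_i`` drawn uniformly from (0, 1), so every Gershgorin disc lies in the
open left half-plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse

__all__ = [
    "LinearNetwork",
    "make_scale_free",
    "make_erdos_renyi",
    "make_random_B",
    "identity_block_B",
    "controllability_ratio",
    "save_network",
    "load_network",
]

TOPOLOGIES = ("scale_free", "erdos_renyi", "custom")


class NetworkConstructionError(ValueError):
    """Raised when a requested network realization cannot be built."""


@dataclass(frozen=True)
class LinearNetwork:
    """A stable linear dynamical network (A, B, Sigma_w) with metadata.

    Attributes
    ----------
    A : (n, n) ndarray
        Adjacency with stabilizing negative diagonal (units 1/time). The
        off-diagonal part is symmetric; every eigenvalue has negative real
        part (checked at construction).
    B : (n, m) ndarray
        Input matrix of full column rank. For the canonical identity-block
        form this is the m x m identity stacked over zeros, with m = n_d.
    Sigma_w : (n, n) ndarray
        Symmetric positive-definite noise covariance (identity by default:
        zero-mean, unit-variance, uncorrelated noise).
    n_d : int
        Number of driver (actuated) nodes.
    topology : str
        One of ``scale_free``, ``erdos_renyi``, ``custom``.
    seed : int or None
        Seed the realization was drawn from, for reproducibility.
    delta : (n,) ndarray or None
        Stability margins delta_i in (0, 1) used to set the diagonal;
        ``None`` for custom systems not built by the generators.
    """

    A: np.ndarray
    B: np.ndarray
    Sigma_w: np.ndarray
    n_d: int
    topology: str = "custom"
    seed: int | None = None
    delta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.asarray(self.B, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        Sw = np.atleast_2d(np.asarray(self.Sigma_w, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Sigma_w", Sw)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError(f"A must be square, got {A.shape}")
        if B.shape[0] != n:
            raise ValueError(f"B has {B.shape[0]} rows but A is {n}x{n}")
        if Sw.shape != (n, n):
            raise ValueError(f"Sigma_w must be {n}x{n}, got {Sw.shape}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (1 <= self.n_d <= n):
            raise ValueError(f"n_d={self.n_d} outside [1, n={n}]")
        if np.any(np.diag(A) >= 0):
            raise ValueError("A must have strictly negative diagonal")
        if not np.allclose(Sw, Sw.T):
            raise ValueError("Sigma_w must be symmetric")
        if np.linalg.eigvalsh(Sw).min() <= 0:
            raise ValueError("Sigma_w must be positive-definite")
        if np.linalg.matrix_rank(B) < B.shape[1]:
            raise ValueError("B must have full column rank")
        if np.linalg.eigvals(A).real.max() >= 0:
            raise ValueError("A is not Hurwitz-stable")

    @property
    def n(self) -> int:
        """Node count."""
        return self.A.shape[0]

    @property
    def m(self) -> int:
        """Input dimension."""
        return self.B.shape[1]

    def degrees(self) -> np.ndarray:
        """Node degrees of the interaction graph (count of nonzero
        off-diagonal couplings per row)."""
        off = self.A - np.diag(np.diag(self.A))
        return (off != 0).sum(axis=1)

    def with_B(self, B: np.ndarray, n_d: int | None = None) -> "LinearNetwork":
        """Return a copy with a different input matrix."""
        B = np.asarray(B, dtype=float)
        return replace(self, B=B, n_d=B.shape[1] if n_d is None else n_d)


def identity_block_B(n: int, n_d: int) -> np.ndarray:
    """The canonical driver-node input matrix: I_{n_d} stacked over zeros.

    Each of the first ``n_d`` nodes receives its own independent input
    channel; the remaining nodes are unactuated.
    """
    if not (1 <= n_d <= n):
        raise ValueError(f"n_d={n_d} outside [1, n={n}]")
    B = np.zeros((n, n_d))
    B[:n_d, :n_d] = np.eye(n_d)
    return B


def _stabilize(off: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Set A_ii = -(sum_{j!=i} A_ij + delta_i), delta_i ~ U(0,1)."""
    n = off.shape[0]
    delta = rng.uniform(0.0, 1.0, size=n)
    A = off.copy()
    np.fill_diagonal(A, -(off.sum(axis=1) + delta))
    return A, delta


def controllability_ratio(net: LinearNetwork) -> float:
    """lambda_min / lambda_max of the infinite-time controllability gramian.

    A strictly positive ratio certifies the pair (A, B) controllable;
    under-actuated networks (n_d << n) routinely return values at or below
    machine precision even though the m-dimensional input-side quadratic
    forms used by the optimization remain well conditioned.
    """
    W = scipy.linalg.solve_continuous_lyapunov(net.A, -net.B @ net.B.T)
    ev = np.linalg.eigvalsh((W + W.T) / 2.0)
    return float(ev.min() / ev.max())


def _finalize(
    off: np.ndarray,
    n_d: int,
    topology: str,
    seed: int | None,
    rng: np.random.Generator,
    sigma_w: np.ndarray | None,
    permute: bool,
    require_connected: bool,
    check_controllability: bool,
    controllability_tol: float,
) -> LinearNetwork:
    n = off.shape[0]
    if require_connected:
        g = nx.from_numpy_array(off != 0)
        if not nx.is_connected(g):
            raise NetworkConstructionError("realization is disconnected")
    if permute:
        perm = rng.permutation(n)
        off = off[np.ix_(perm, perm)]
    A, delta = _stabilize(off, rng)
    Sw = np.eye(n) if sigma_w is None else np.asarray(sigma_w, dtype=float)
    net = LinearNetwork(
        A=A, B=identity_block_B(n, n_d), Sigma_w=Sw,
        n_d=n_d, topology=topology, seed=seed, delta=delta,
    )
    if check_controllability:
        ratio = controllability_ratio(net)
        if ratio <= controllability_tol:
            raise NetworkConstructionError(
                f"gramian conditioning {ratio:.2e} <= tol {controllability_tol:.2e}"
            )
    return net


def _scale_free_offdiag(
    n: int, m_attach: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    gseed = int(rng.integers(0, 2**31 - 1))
    if method == "ba":
        g = nx.barabasi_albert_graph(n, m_attach, seed=gseed)
    elif method == "configuration":
        # draw a scale-free degree sequence, then wire a matching random
        # graph (multi-edges/self-loops collapsed to simple edges)
        local = np.random.default_rng(gseed)
        gamma = 2.5
        deg = np.clip(local.zipf(gamma, size=n), 1, n - 1)
        if deg.sum() % 2:
            deg[int(local.integers(n))] += 1
        g = nx.Graph(nx.configuration_model(deg.tolist(), seed=gseed))
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise ValueError(f"unknown scale-free method {method!r}")
    return nx.to_numpy_array(g, nodelist=range(n))


def make_scale_free(
    n: int,
    n_d: int,
    seed: int,
    *,
    m_attach: int = 2,
    method: str = "ba",
    sigma_w: np.ndarray | None = None,
    permute: bool = True,
    require_connected: bool = False,
    check_controllability: bool = False,
    controllability_tol: float = 1e-12,
    max_tries: int = 10,
) -> LinearNetwork:
    """Generate a stable scale-free (Barabási–Albert) network realization.

    Off-diagonal couplings are binary and symmetric, from preferential
    attachment with ``m_attach`` edges per arriving node (or, with
    ``method='configuration'``, a configuration-model graph drawn from a
    power-law degree sequence). Diagonal entries are set to
    ``-(row degree + delta_i)`` with ``delta_i ~ U(0, 1)``. The input matrix
    is the identity block over the first ``n_d`` nodes; node labels are
    randomly permuted first (``permute=True``) so the actuated subset is not
    tied to the generator's arrival order.

    Parameters
    ----------
    n, n_d : int
        Node count (>= 3) and driver count (1 <= n_d <= n).
    seed : int
        Seeds the whole construction; identical arguments give a
        bit-identical network.
    check_controllability : bool
        If True, resample (up to ``max_tries``) until the infinite-time
        gramian satisfies ``lambda_min > controllability_tol * lambda_max``.
        Off by default: under-actuated networks are numerically singular in
        the unactuated subspace by nature, not by pathology.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not (1 <= n_d <= n):
        raise ValueError(f"n_d={n_d} outside [1, n={n}]")
    rng = np.random.default_rng(seed)
    last: Exception | None = None
    for _ in range(max_tries):
        off = _scale_free_offdiag(n, m_attach, rng, method)
        try:
            return _finalize(
                off, n_d, "scale_free", seed, rng, sigma_w, permute,
                require_connected, check_controllability, controllability_tol,
            )
        except NetworkConstructionError as exc:
            last = exc
    raise NetworkConstructionError(
        f"no admissible realization in {max_tries} tries: {last}"
    )


def make_erdos_renyi(
    n: int,
    n_d: int,
    p: float,
    seed: int,
    *,
    weight_range: tuple[float, float] = (0.001, 0.1),
    sigma_w: np.ndarray | None = None,
    permute: bool = True,
    require_connected: bool = False,
    check_controllability: bool = False,
    controllability_tol: float = 1e-12,
    max_tries: int = 10,
) -> LinearNetwork:
    """Generate a stable Erdős–Rényi network with small positive weights.

    Each undirected edge is present independently with probability ``p`` and
    carries a weight drawn uniformly from ``weight_range`` (default
    (0.001, 0.1): small positive weights keep dense random graphs numerically
    tractable). Diagonal, input matrix and permutation as in
    :func:`make_scale_free`.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"edge probability p={p} outside (0, 1]")
    if not (1 <= n_d <= n):
        raise ValueError(f"n_d={n_d} outside [1, n={n}]")
    lo, hi = weight_range
    if not (0.0 < lo < hi):
        raise ValueError("weight_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    last: Exception | None = None
    for _ in range(max_tries):
        gseed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnp_random_graph(n, p, seed=gseed)
        off = np.zeros((n, n))
        for i, j in g.edges():
            w = rng.uniform(lo, hi)
            off[i, j] = off[j, i] = w
        try:
            return _finalize(
                off, n_d, "erdos_renyi", seed, rng, sigma_w, permute,
                require_connected, check_controllability, controllability_tol,
            )
        except NetworkConstructionError as exc:
            last = exc
    raise NetworkConstructionError(
        f"no admissible realization in {max_tries} tries: {last}"
    )


def make_random_B(n: int, m: int, seed: int) -> np.ndarray:
    """Random dense input matrix: i.i.d. standard-normal entries with
    unit-normalized columns (full column rank almost surely; re-drawn in the
    measure-zero event it is not).

    Column normalization keeps the per-channel input energy comparable to
    the identity-block case.
    """
    if not (1 <= m <= n):
        raise ValueError(f"m={m} outside [1, n={n}]")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        B = rng.standard_normal((n, m))
        if np.linalg.matrix_rank(B) == m:
            return B / np.linalg.norm(B, axis=0)
    raise NetworkConstructionError("could not draw a full-rank B")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization: Matrix Market matrices + JSON sidecar

def save_network(net: LinearNetwork, directory: str | Path) -> Path:
    """Write A, B, Sigma_w as Matrix Market files plus JSON metadata.

    Also writes ``edges.tsv`` (i, j, weight for the upper-triangular
    off-diagonal couplings) for use with graph tooling.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "A.mtx", scipy.sparse.coo_matrix(net.A))
    scipy.io.mmwrite(d / "B.mtx", scipy.sparse.coo_matrix(net.B))
    scipy.io.mmwrite(d / "Sigma_w.mtx", scipy.sparse.coo_matrix(net.Sigma_w))
    meta = {
        "n": net.n,
        "m": net.m,
        "n_d": net.n_d,
        "topology": net.topology,
        "seed": net.seed,
        "delta": None if net.delta is None else net.delta.tolist(),
    }
    (d / "network.json").write_text(json.dumps(meta, indent=1))
    off = net.A - np.diag(np.diag(net.A))
    with open(d / "edges.tsv", "w") as fh:
        fh.write("source\ttarget\tweight\n")
        ii, jj = np.nonzero(np.triu(off))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{off[i, j]:.17g}\n")
    return d


def load_network(directory: str | Path) -> LinearNetwork:
    """Inverse of :func:`save_network`."""
    d = Path(directory)
    meta = json.loads((d / "network.json").read_text())
    A = np.asarray(scipy.io.mmread(d / "A.mtx").todense())
    B = np.asarray(scipy.io.mmread(d / "B.mtx").todense())
    Sw = np.asarray(scipy.io.mmread(d / "Sigma_w.mtx").todense())
    delta = meta.get("delta")
    return LinearNetwork(
        A=A, B=B, Sigma_w=Sw, n_d=meta["n_d"], topology=meta["topology"],
        seed=meta["seed"], delta=None if delta is None else np.asarray(delta),
    )
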