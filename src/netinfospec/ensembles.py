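"""Seeded multi-realization experiments over network ensembles.

Each experiment regenerates a seeded ensemble of networks, runs the
Rayleigh-quotient optimizations on every realization, and returns a tidy
DataFrame (one row per realization x condition) that downstream summaries
and plots aggregate. Realization seeds are derived deterministically from
the experiment seed, so a run manifest (parameters + seed + versions)
reproduces every table bitwise.

The experiments mirror four analyses:

* alignment of the optimal background x_ref with the principal noise axis
  v_max of Sigma_x, as a function of the driver count n_d, whole-vector and
  partitioned into actuated vs non-actuated nodes;
* the time course of that alignment (covariance held at steady state while
  the propagator Gamma(t) evolves);
* hub-targeting profiles of the optimal input u_ref: squared entries
  binned by the degree percentile of the actuated node they drive;
* pooled information spectra (eigenvalues of S_u) against controllability-
  gramian spectra (eigenvalues of W(inf)).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .lindyn import gamma_matrix, gramian, steady_covariance
from .netgen import LinearNetwork, make_erdos_renyi, make_random_B, make_scale_free
from .optima import alignment_cosine, optimal_uref, optimal_xref

__all__ = [
    "alignment_experiment",
    "summarize_alignment",
    "time_course_experiment",
    "hub_profile_experiment",
    "summarize_hub_profile",
    "spectrum_experiment",
    "SpectrumEnsemble",
    "run_manifest",
]

DEFAULT_REALIZATIONS = 30
BIN_WIDTH_PCT = 5.0


def _spawn_seeds(seed: int, k: int) -> np.ndarray:
    """k deterministic child seeds in [0, 2^31)."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)


def _make_net(topology: str, n: int, n_d: int, seed: int, p: float) -> LinearNetwork:
    if topology == "scale_free":
        return make_scale_free(n, n_d, int(seed))
    if topology == "erdos_renyi":
        return make_erdos_renyi(n, n_d, p, int(seed))
    raise ValueError(f"unknown topology {topology!r}")


def _v_max(sigma_x: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((sigma_x + sigma_x.T) / 2.0)
    return V[:, -1]


def _signed_cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# alignment of x_ref_opt with the principal noise axis


def alignment_experiment(
    n_list: Sequence[int],
    nd_list: Sequence[int],
    *,
    t: float = 10.0,
    realizations: int = DEFAULT_REALIZATIONS,
    seed: int = 0,
    b_variants: Sequence[str] = ("identity",),
    topology: str = "scale_free",
    p: float = 0.5,
) -> pd.DataFrame:
    """Alignment of the optimal background with v_max over an ensemble.

    For every (n, n_d, B-variant) condition and realization, computes the
    optimal x_ref and records its alignment cosine with the principal
    eigenvector of Sigma_x: whole-vector (``cos_full``, absolute cosine)
    and, for the identity-block B (where the actuated set is the first n_d
    coordinates), partitioned into actuated (``cos_actuated``) and
    non-actuated (``cos_nonactuated``) nodes. Partition cosines are
    *signed*, under a common orientation (x_ref flipped so its full inner
    product with v_max is nonnegative): the optimal background carries
    almost no mass on non-actuated nodes, and the absolute cosine of that
    near-zero residual is uninformative about whether the partition is
    required to track v_max — the signed value under a fixed orientation
    is. ``b_variants`` may include ``"identity"`` and ``"random"`` (a dense
    random n x n_d input matrix, for which the partition is undefined and
    recorded as NaN).
    """
    if realizations < 2:
        raise ValueError("need at least 2 realizations")
    rows = []
    for n in n_list:
        for n_d in nd_list:
            if n_d > n:
                continue
            seeds = _spawn_seeds(seed + 1_000_003 * n + n_d, realizations)
            for r, s in enumerate(seeds):
                try:
                    net = _make_net(topology, n, n_d, s, p)
                except Exception as exc:  # construction failures carry context
                    raise RuntimeError(
                        f"realization {r} of (n={n}, n_d={n_d}) failed"
                    ) from exc
                sigma_x = steady_covariance(net)
                gamma = gamma_matrix(net, t)
                vmax = _v_max(sigma_x)
                for variant in b_variants:
                    if variant == "identity":
                        vnet = net
                    elif variant == "random":
                        vnet = net.with_B(make_random_B(n, n_d, int(s) + 1), n_d=n_d)
                    else:
                        raise ValueError(f"unknown B variant {variant!r}")
                    x_opt, lam, _ = optimal_xref(vnet, t, gamma=gamma, sigma_x=sigma_x)
                    cos_full = alignment_cosine(x_opt, vmax)
                    if variant == "identity":
                        if x_opt @ vmax < 0:
                            x_opt = -x_opt
                        cos_a = _signed_cosine(x_opt[:n_d], vmax[:n_d])
                        cos_na = (
                            _signed_cosine(x_opt[n_d:], vmax[n_d:])
                            if n_d < n
                            else np.nan
                        )
                    else:
                        cos_a = cos_na = np.nan
                    rows.append(
                        dict(
                            n=n, n_d=n_d, t=t, b_variant=variant,
                            realization=r, seed=int(s), lambda_max=lam,
                            cos_full=cos_full, cos_actuated=cos_a,
                            cos_nonactuated=cos_na,
                        )
                    )
    return pd.DataFrame(rows)


def summarize_alignment(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of the cosines per condition."""
    return (
        df.groupby(["n", "n_d", "b_variant", "t"], as_index=False)
        .agg(
            mean_cos_full=("cos_full", "mean"),
            std_cos_full=("cos_full", "std"),
            mean_cos_actuated=("cos_actuated", "mean"),
            mean_cos_nonactuated=("cos_nonactuated", "mean"),
            realizations=("realization", "count"),
        )
    )


def time_course_experiment(
    n: int,
    nd_list: Sequence[int],
    t_grid: Sequence[float],
    *,
    realizations: int = DEFAULT_REALIZATIONS,
    seed: int = 0,
    topology: str = "scale_free",
    p: float = 0.5,
) -> pd.DataFrame:
    """Alignment of x_ref_opt with v_max across evaluation times.

    The steady-state covariance (and hence v_max and the whitening factor)
    is fixed per realization; only the propagator Gamma(t) varies along
    ``t_grid``, so the table isolates the dynamical evolution of the
    optimal background's orientation.
    """
    t_grid = list(t_grid)
    if any(tb <= ta for ta, tb in zip(t_grid, t_grid[1:])) or t_grid[0] <= 0:
        raise ValueError("t_grid must be positive and strictly increasing")
    rows = []
    for n_d in nd_list:
        seeds = _spawn_seeds(seed + 1_000_003 * n + n_d, realizations)
        for r, s in enumerate(seeds):
            net = _make_net(topology, n, n_d, s, p)
            sigma_x = steady_covariance(net)
            vmax = _v_max(sigma_x)
            for t in t_grid:
                gamma = gamma_matrix(net, t)
                x_opt, lam, _ = optimal_xref(net, t, gamma=gamma, sigma_x=sigma_x)
                rows.append(
                    dict(
                        n=n, n_d=n_d, t=t, realization=r, seed=int(s),
                        lambda_max=lam,
                        cos_full=alignment_cosine(x_opt, vmax),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hub-targeting profiles of u_ref_opt


def _degree_percentile_bins(degrees: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Map per-node weights to 5%-wide degree-percentile bins (descending
    degree) among the actuated nodes.

    Node k in the degree-descending order (ties broken by node index) owns
    the percentile interval [100 k / n_d, 100 (k+1) / n_d). A bin's value is
    the mean weight of the nodes whose interval midpoint falls inside it;
    when there are fewer nodes than bins, the node covering the bin midpoint
    is used, so consecutive bins duplicate values rather than sit empty.
    """
    n_d = degrees.size
    order = np.lexsort((np.arange(n_d), -degrees))
    w_sorted = weights[order]
    n_bins = int(round(100.0 / BIN_WIDTH_PCT))
    out = np.empty(n_bins)
    mids = (np.arange(n_d) + 0.5) / n_d * 100.0
    for b in range(n_bins):
        lo, hi = b * BIN_WIDTH_PCT, (b + 1) * BIN_WIDTH_PCT
        inside = (mids >= lo) & (mids < hi)
        if inside.any():
            out[b] = w_sorted[inside].mean()
        else:
            k = min(int((lo + hi) / 2 / 100.0 * n_d), n_d - 1)
            out[b] = w_sorted[k]
    return out


def hub_profile_experiment(
    n_list: Sequence[int],
    nd_fractions: Sequence[float],
    *,
    topology: str = "scale_free",
    p: float = 0.5,
    t: float = 10.0,
    realizations: int = DEFAULT_REALIZATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Degree-percentile profiles of the optimal input's energy.

    Per realization the unit-norm u_ref_opt is computed, its squared
    entries (which sum to one — the input's energy budget) are attributed
    to the actuated nodes they drive, and the per-node energies are binned
    by the node's degree percentile among actuated nodes (top bin = top 5%
    by degree). Returned rows: one per (n, n_d, realization, bin).
    """
    rows = []
    n_bins = int(round(100.0 / BIN_WIDTH_PCT))
    centers = (np.arange(n_bins) + 0.5) * BIN_WIDTH_PCT
    for n in n_list:
        for frac in nd_fractions:
            n_d = max(1, int(round(frac * n)))
            seeds = _spawn_seeds(seed + 1_000_003 * n + n_d, realizations)
            for r, s in enumerate(seeds):
                net = _make_net(topology, n, n_d, s, p)
                u_opt, _, _ = optimal_uref(net, t)
                energy = u_opt**2
                deg_act = net.degrees()[: net.n_d].astype(float)
                mu = _degree_percentile_bins(deg_act, energy)
                for b in range(n_bins):
                    rows.append(
                        dict(
                            n=n, n_d=n_d, topology=topology, realization=r,
                            seed=int(s), bin=b, percentile=centers[b],
                            mu=mu[b],
                        )
                    )
    return pd.DataFrame(rows)


def summarize_hub_profile(df: pd.DataFrame) -> pd.DataFrame:
    """Mean per-bin energy mu_i over realizations, per condition."""
    return (
        df.groupby(["n", "n_d", "topology", "bin", "percentile"], as_index=False)
        .agg(mu=("mu", "mean"), std=("mu", "std"))
    )


# ---------------------------------------------------------------------------
# pooled information and gramian spectra


@dataclass(frozen=True)
class SpectrumEnsemble:
    """Pooled eigenvalue samples over seeded realizations.

    ``source`` is ``"information"`` (eigenvalues of S_u; m per realization)
    or ``"gramian"`` (eigenvalues of W(inf); n per realization). The two
    live in different spaces (m- vs n-dimensional) and are never pooled
    together.
    """

    source: str
    samples: np.ndarray
    table: pd.DataFrame  # one row per eigenvalue: n, n_d, realization, value
    n_list: tuple[int, ...]
    nd_fraction: float
    realizations: int

    def histogram(self, bins: int | str = "fd") -> tuple[np.ndarray, np.ndarray]:
        """Histogram of log10 eigenvalues (Freedman–Diaconis by default;
        the modes span orders of magnitude). Returns (counts, edges)."""
        positive = self.samples[self.samples > 0]
        return np.histogram(np.log10(positive), bins=bins)


def spectrum_experiment(
    n_list: Sequence[int],
    nd_fraction: float,
    *,
    t: float = 10.0,
    realizations: int = DEFAULT_REALIZATIONS,
    seed: int = 0,
    topology: str = "scale_free",
    p: float = 0.5,
) -> tuple[SpectrumEnsemble, SpectrumEnsemble]:
    """Pooled information spectrum (eigenvalues of S_u) and gramian
    spectrum (eigenvalues of W(inf)) over realizations and sizes."""
    info_rows, gram_rows = [], []
    for n in n_list:
        n_d = max(1, int(round(nd_fraction * n)))
        seeds = _spawn_seeds(seed + 1_000_003 * n + n_d, realizations)
        for r, s in enumerate(seeds):
            net = _make_net(topology, n, n_d, s, p)
            sigma_x = steady_covariance(net)
            gamma = gamma_matrix(net, t)
            _, _, prob = optimal_uref(net, t, gamma=gamma, sigma_x=sigma_x)
            for lam in prob.eigenvalues:
                info_rows.append(
                    dict(n=n, n_d=n_d, realization=r, seed=int(s), value=float(lam))
                )
            for lam in np.linalg.eigvalsh(gramian(net, np.inf)):
                gram_rows.append(
                    dict(n=n, n_d=n_d, realization=r, seed=int(s), value=float(lam))
                )
    info_df = pd.DataFrame(info_rows)
    gram_df = pd.DataFrame(gram_rows)
    mk = lambda src, df: SpectrumEnsemble(  # noqa: E731
        source=src,
        samples=df["value"].to_numpy(),
        table=df,
        n_list=tuple(int(x) for x in n_list),
        nd_fraction=float(nd_fraction),
        realizations=realizations,
    )
    return mk("information", info_df), mk("gramian", gram_df)


# ---------------------------------------------------------------------------
# reproducibility manifest


def run_manifest(experiment: str, seed: int, params: dict) -> dict:
    """Everything needed to reproduce a run bitwise: experiment name,
    master seed, parameters, and software versions."""
    import networkx
    import scipy

    return {
        "experiment": experiment,
        "seed": int(seed),
        "params": params,
        "versions": {
            "python": platform.python_version(),
            "netinfospec": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
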