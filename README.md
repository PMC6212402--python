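# netinfospec

Fisher information spectra and optimal background states for noisy linear
dynamical networks.

## The problem

How well does the state of a recurrent network encode its inputs? Consider a
stable linear dynamical network driven by a constant stimulus and white
state noise,

```
dx/dt = A x + B u + w(t),        w ~ N(0, Σ_w),
```

with `A` an n×n coupling matrix (symmetric adjacency plus a stabilizing
negative diagonal), `B` an n×m input matrix routing the m-dimensional
stimulus `u` onto a subset of n_d "driver" nodes, and noise held at its
stationary distribution. A downstream observer reads out only the scalar
projection `⟨x(t), x_ref⟩` of the state onto a fixed background ("resting")
state `x_ref` — the kind of highly condensed readout studied in neural
population coding. The question this package answers quantitatively: which
background state, and which stimulus, make that readout maximally
informative, and how do the answers depend on network structure (scale-free
vs random topology), on how many nodes receive input, and on time?

Intended users: researchers in network control theory, theoretical
neuroscience, and systems biology who work with linear(ized) network models.

## The method

Because `x(t) ~ N(Γ(t) B u, Σ_x)` with propagator `Γ(t) = ∫₀ᵗ e^{A(t−τ)} dτ`
and steady-state covariance `Σ_x` (the Lyapunov solution of
`A Σ_x + Σ_x Aᵀ + Σ_w = 0`), the readout is Gaussian with mean
`x_refᵀ Γ B u` and variance `x_refᵀ Σ_x x_ref` — the stimulus cancels out of
the variance. The Fisher information matrix for `u` given the readout is the
rank-one form

```
I_u = (Bᵀ Γᵀ x_ref)(x_refᵀ Γ B) / (x_refᵀ Σ_x x_ref),
tr(I_u) = x_refᵀ Γ B Bᵀ Γᵀ x_ref / (x_refᵀ Σ_x x_ref),
```

a generalized Rayleigh quotient in `x_ref`. Whitening with the Cholesky
factor `L Lᵀ = Σ_x` reduces it to an ordinary Rayleigh quotient of
`S = L⁻¹ Γ B Bᵀ Γᵀ L⁻ᵀ`; the optimal background is the back-transformed
principal eigenvector — a Fisher linear discriminant of the
stimulus-induced state distributions. Restricting backgrounds to those
reachable by a constant input (`x_ref = Γ B u_ref`) gives the analogous
m-dimensional problem whose matrix `S_u` has the *information spectrum* as
its eigenvalues: eigenvalue i is the readout information attained by the
i-th whitened input direction. The package also computes controllability
gramians `W(t)` — equal to `Σ_x` when `Σ_w = B Bᵀ` — so information spectra
can be compared with the control-theoretic energy spectrum of the same
networks, plus a seeded Euler–Maruyama / exact-Gaussian trajectory
simulator used as an empirical oracle for the analytic results.

## Worked example

```python
import numpy as np
from netinfospec import (
    make_scale_free, optimal_xref, optimal_uref, fisher_trace,
    steady_covariance, information_spectrum,
)
from netinfospec.optima import alignment_cosine

net = make_scale_free(n=100, n_d=10, seed=1)      # 10 driver nodes
x_ref, lam, _ = optimal_xref(net, t=10.0)
v_max = np.linalg.eigh(steady_covariance(net))[1][:, -1]
print(f"lambda_max (best attainable tr I_u): {lam:.4f}")
print(f"tr I_u at x_ref_opt:                 {fisher_trace(net, x_ref, 10.0):.4f}")
print(f"cos(x_ref_opt, v_max):               {alignment_cosine(x_ref, v_max):.4f}")
u_ref, lam_u, _ = optimal_uref(net, t=10.0)
spec = information_spectrum(net, 10.0)
print(f"best input-induced tr I_u:           {lam_u:.4f}")
print(f"information spectrum (m={net.m}):      [{spec.min():.4f}, {spec.max():.4f}]")
```

prints

```
lambda_max (best attainable tr I_u): 1.0509
tr I_u at x_ref_opt:                 1.0509
cos(x_ref_opt, v_max):               0.2346
best input-induced tr I_u:           0.9375
information spectrum (m=10):      [0.1002, 0.9375]
```

The best unconstrained background achieves information 1.05 per readout
sample; the solver's eigenvalue and the directly evaluated trace agree. With
only 10 of 100 nodes actuated, the optimal background is far from the
principal noise axis (cosine 0.23 — it concentrates on the actuated nodes
instead), and the best input-induced background recovers most (0.94/1.05)
of the unconstrained optimum. The information spectrum spans the
per-direction information of all 10 whitened input channels.

Ensemble experiments (alignment vs driver count, time courses,
hub-targeting profiles of the optimal input, pooled information/gramian
spectra) live in `netinfospec.ensembles` and are also exposed on the
command line:

```
netinfospec netgen --topology ba --n 100 --nd 10 --seed 1 --out net/
netinfospec run alignment --config examples/alignment.yaml --out results/ --seed 1
```

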