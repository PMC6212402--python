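# Methods

## Model and assumptions

The package analyzes stable linear stochastic networks

    dx/dt = A x + B u + w(t),    w ~ N(0, Σ_w),    u constant,

under three standing assumptions:

1. **Stationary noise.** The network is persistently excited by the noise,
   and stimuli arrive punctately, so the state covariance is always the
   steady-state Lyapunov solution Σ_x of A Σ + Σ Aᵀ + Σ_w = 0 even when the
   deterministic response Γ(t) B u is evaluated at finite t. A finite-time
   covariance is available (`lindyn.finite_time_covariance`) but is never
   used in the analysis pipeline.
2. **Constant stimuli.** The Fisher analysis differentiates the readout
   mean with respect to a constant u; time-varying inputs are out of scope.
3. **Controllable, stable (A, B).** Stability is enforced constructively by
   the generators (below). The m×m denominator form BᵀΓᵀΣ_xΓB used by the
   input-side optimization is positive-definite whenever Σ_x is PD and ΓB
   has full column rank, which holds for every generated system; the n×n
   infinite-time gramian, by contrast, is numerically singular for
   under-actuated networks (n_d ≪ n) as a matter of course, so the package
   reports a conditioning diagnostic (`netgen.controllability_ratio`)
   rather than rejecting such networks.

## Network generators

Two seeded topology families, both undirected, with the input applied
through the identity block B = [I_{n_d}; 0] (a dense random B with
unit-norm columns is available for comparison experiments):

- **Scale-free**: Barabási–Albert preferential attachment with
  `m_attach = 2` edges per arriving node (a configuration-model variant
  drawn from a power-law degree sequence is exposed as an option), binary
  symmetric couplings. The attachment parameter is a modeling choice; 2
  gives connected graphs with the characteristic hub-dominated degree
  distribution at the sizes used here (20–400 nodes).
- **Erdős–Rényi**: each edge present independently with probability p
  (default 0.5) and weight drawn Uniform(0.001, 0.1). Small positive
  weights keep dense random graphs comparable in coupling scale to the
  sparse binary scale-free case; the lower bound merely excludes
  numerically-zero edges. The exact weight distribution below 0.1 is a free
  choice; uniform is the least-informative option.

Stability margin: A_ii = −(Σ_{j≠i} A_ij + δ_i) with δ_i ~ Uniform(0, 1)
drawn once per realization and stored on the network object, so every
Gershgorin disc lies strictly in the left half-plane and the margin is
inspectable. Note the consequence: the slowest relaxation rate of a
realization is of order min_i δ_i, whose expectation scales like 1/n — large
networks generically contain one very slow collective mode.

**Driver choice.** Node labels are randomly permuted (seeded) before B is
applied, so the actuated subset is a uniform random subset of nodes rather
than the generator's arrival-order prefix (for preferential attachment the
earliest nodes are systematically the hubs, which would bias every
driver-placement statistic).

**Default noise** is Σ_w = I (unit-variance, uncorrelated); any symmetric
PD covariance may be supplied.

## Linear-system computations

- Γ(t) = A⁻¹(e^{At} − I) when cond(A) < 1e8, otherwise the top-right block
  of exp([[A, I], [0, 0]]t), which needs no inversion.
- Finite-time integrals ∫₀ᵗ e^{As} Q e^{Aᵀs} ds (gramian, finite-time
  covariance) use the decay identity X(t) = X(∞) − e^{At} X(∞) e^{Aᵀt} for
  stable A — only decaying exponentials appear, so accuracy is uniform in
  t. The Van Loan augmented-exponential block identity is kept for the
  non-stable case and for the small-step noise integral of the exact
  simulator; its augmented matrix contains growing modes e^{+|λ|t} and is
  unusable at large t.
- Lyapunov equations are solved with SciPy's Bartels–Stewart solver and
  symmetrized.

## The optimizations

tr(I_u) is a ratio of quadratic forms; both optimizations whiten by the
lower Cholesky factor of the denominator matrix and take the principal
eigenvector of the resulting symmetric matrix (S in state space, S_u in
input space), back-transforming through L⁻ᵀ and normalizing to unit length
(the trace is scale-invariant; unit norm makes realizations comparable, and
the optimal input is unit-energy by convention). Numerical policy:

- matrices are symmetrized ((M + Mᵀ)/2) before eigendecomposition; PSD-ness
  is asserted up to −1e−10 of the top eigenvalue;
- if a Cholesky factorization fails, one retry with 1e−12·trace jitter is
  attempted and logged; failure raises an error naming the offending
  matrix;
- eigenvector signs are fixed by making the largest-magnitude component
  positive; a (near-)degenerate top eigenvalue (gap ≤ 1e−10 relative) is
  flagged on the result object and the deterministic eigensolver's vector
  is returned;
- a readout whose variance falls below 1e−14·‖x_ref‖²·λ_max(Σ_x) raises a
  degenerate-readout error rather than returning a huge ratio.

An independent route — SciPy's generalized symmetric eigensolver on
(ΓBBᵀΓᵀ, Σ_x) — and brute-force random search plus power-iteration
refinement are used as oracles in the tests, never as the implementation.

## Alignment statistics

`alignment_cosine` is the absolute cosine of the angle between two
(sub)vectors — absolute because eigenvector-valued arguments carry an
arbitrary sign. For the actuated/non-actuated partition analysis the
absolute value is deliberately *not* used: the optimal background carries
almost all of its norm on the actuated coordinates (the non-actuated
residual is O(1e−3) of the vector at the default conditions), and the
absolute cosine of a normalized near-zero residual says nothing about
whether that partition is required to track the noise axis. The ensemble
tables therefore record partition cosines *signed*, under a common
orientation (x_ref flipped so its full inner product with v_max is
nonnegative). Under this measure the actuated partition tracks v_max
(mean ≈ +0.84 at n=100, n_d=10) while the non-actuated residual does not
(≈ −1.0), which is the substantive contrast: informativeness constrains the
background only where the input can act.

## Hub-profile binning

The optimal input's squared entries (its energy budget: they sum to 1) are
attributed to the actuated nodes they drive and binned by the node's degree
percentile **among actuated nodes** (entries of u_ref map one-to-one onto
actuated nodes; ranking against all nodes would mix in nodes the input
cannot touch). Bins are 5% wide, highest degree first, ties broken by node
index. When n_d < 20 a node's percentile interval spans several bins and
its value is repeated in each, so the profile always has 20 bins.

A structural result worth stating because the test suite and acceptance
script measure it directly: at full actuation (B = I, symmetric A, steady
state) the generalized problem reduces to the eigenproblem of A itself, and
the information-*maximizing* input is A's slowest mode — a smooth,
near-uniform vector (top-5%-degree bin ≈ the uniform share, for scale-free
and ER alike). Degree-targeted energy profiles instead appear for
*under-actuated* networks, where reaching the slow collective modes
requires leaning on well-connected actuated nodes: at n_d = n/10 the
top-bin-to-median ratio is ≈ 9.6 for scale-free vs ≈ 1.8 for ER ensembles
(n = 400, 10 realizations). The fastest, most noise-suppressed directions —
the *minimizing* end of the spectrum — are the ones that localize on the
highest-degree hub; they are the most expensive to reach and the least
informative under this readout.

## Spectra

The information spectrum is the full eigenvalue set of S_u (m per
realization); the gramian spectrum is the eigenvalue set of W(∞) (n per
realization). The two live in different spaces and are never pooled.
Histograms are taken on log10 eigenvalues with Freedman–Diaconis bins,
since the modes span orders of magnitude; raw samples are always exported
so binning is cosmetic. No formal multimodality testing is attempted.

## Trajectory simulator

Euler–Maruyama (default) with increments N(0, Σ_w dt); the step is refused
if dt·max|Re eig(A)| > 0.1. An exact Gaussian one-step sampler (e^{A dt},
dt-step propagator, dt-step Lyapunov integral via Van Loan) is provided as
a bias-free cross-check and for cheap long-horizon sampling. Paths start
from the exact stationary distribution N(0, Σ_x) by default (the regime the
analysis assumes); a zero start with a burn-in of ten slowest time
constants is available. Defaults: dt = 1e−3, 1000 paths.

## Ensemble sizes and determinism

The canonical ensemble size is 30 realizations per condition; the shipped
tests and the acceptance script use 10 (and networks of 10–400 nodes),
sizes at which every trend statistic they assert is stable across seeds
while the whole suite runs in well under a minute. All experiment seeds are
derived deterministically from a single master seed; a run manifest
(parameters, seed, package versions) is emitted so any table can be
regenerated bitwise.

## Known limitations

- Linear dynamics only; the analysis is a local approximation for any real
  biological network.
- Constant inputs only; time-varying stimuli would require a basis
  expansion of u(t) and are not implemented.
- Undirected topologies with the stated weight conventions; no directed,
  degree-corrected, or weighted scale-free variants.
- The synthetic ensembles emulate topology and actuation structure, not any
  measured biological connectome or resting-state data: passing tests show
  the mathematics and its trends are implemented correctly, not that a
  particular biological network behaves this way.
- The inner product is the only readout considered; nothing is claimed
  about whether a network could itself implement this readout.
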