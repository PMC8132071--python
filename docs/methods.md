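# Methods

## Model

Networks are Hill-kinetics ODE systems.  Component i evolves as

    dx_i/dt = f_i(x) = Σ_j A[j,i] · x_j^n / (S[j,i]^n + x_j^n)
            + Σ_j B[j,i] · S[j,i]^n / (S[j,i]^n + x_j^n)
            − k_i x_i + g0_i

with activation strengths A, inhibition strengths B (an "inhibition" is
a synthesis term that is large while the inhibitor is low), Hill
threshold S (scalar or per-link matrix), Hill coefficient n,
degradation k and basal rate g0.  A given ordered pair (j, i) may carry
at most one sign.  Stochasticity is additive Gaussian white noise with
constant, homogeneous diffusion coefficient d: each component receives
independent increments of variance 2·d·dt (a Langevin equation whose
density obeys the corresponding Fokker–Planck equation).

States are concentrations.  Hill terms are evaluated on max(x, 0) and
the stochastic integrator clamps at zero; this convention matters only
when an attractor sits within a few noise standard deviations of the
axis (see Limitations).

## Gaussian-mixture closure

Solving the Fokker–Planck equation directly is infeasible beyond a few
dimensions.  Instead, for small d the density near each stable fixed
point x* is approximated by a Gaussian: the mean follows the
deterministic flow (so sits at x* in steady state) and the covariance
obeys dΣ/dt = JΣ + ΣJᵀ + 2dI with J the Jacobian at the mean.  At
steady state this is the algebraic Lyapunov equation, which we solve
directly (`scipy.linalg.solve_lyapunov`); time integration of the
covariance ODE is available as an alternative route and agrees to
numerical precision — the algebraic solve is the default because it has
no integration error.  A multistable system becomes a weighted mixture:
one component per attractor, weighted by the fraction of random initial
conditions its basin captures.  Components are never pruned, however
small their weight, so shallow basins remain visible on landscapes.

Validity requires components narrow relative to inter-attractor
distances.  `MixtureDensity.spread_diagnostic()` reports the ratio of
the largest component standard deviation to the smallest inter-mean
distance; no hard cutoff is imposed, the number is informational.

## Attractor search

Initial conditions are sampled uniformly in [0, x_max]^N with
x_max = 1.2 · (incoming strengths + g0)/k per node — an upper bound on
any steady state since Hill terms are ≤ 1.  The ensemble is relaxed
with fixed-step RK4 (dt = 0.05 to t = 80; the relaxation only needs to
deliver each start into its basin), endpoints are Newton-polished
(`scipy.optimize.root`, analytic Jacobian), roots accepted when the
residual infinity-norm is below 1e-8, deduplicated at relative L∞ 1e-4,
and kept when all Jacobian eigenvalues have real part below −1e-9.
Starts that fail to converge to a stable root (slow manifolds near
saddles) are excluded from the weights with a warning; an error is
raised only when no stable state exists (limit cycles, divergence).
Default 1000 starts; weights carry the binomial standard error of that
sample size.

## Dimension reduction

The mixture's global moments are μ = Σ φ_j μ_j and
Σ = Σ φ_j (Σ_j + μ_j μ_jᵀ) − μμᵀ.  Eigendecomposition of Σ (symmetric
eigensolver, eigenvalues sorted descending, stable sort on ties) gives
the orthonormal principal axes W; each eigenvector's sign is fixed so
its largest-magnitude entry is positive.  A "contribution rate" is an
eigenvalue's percentage of the trace.  Because the transform is
orthogonal and linear, the projected mixture is closed-form: component
j keeps weight φ_j, mean WCᵀμ_j and covariance WCᵀΣ_jWC for the
retained columns WC.  The reduced landscape U = −ln p is evaluated on a
regular grid spanning the projected means ± 3 projected standard
deviations per axis (default resolution 200 per axis, capped at
u_cap = 50 where the density underflows; eigenvalues below 1e-12·λ1 are
reported as 0% contribution).  Both raw and min-shifted potentials are
available; outputs record which mode was used.

## Landscape quantification

Saddles between gridded basins use sorted-cell union-find flooding:
cells are activated in order of increasing U, and the level at which
the two basins' sublevel components first merge is the minimax saddle
level (8-neighbor connectivity in 2D, 2-neighbor in 1D).  Barrier
height is BH = |U_saddle − U_stable| per basin; the signed difference
of two basin potentials is the relative barrier height.

Reference landscapes come from Euler–Maruyama simulation (fixed
dt = 0.01 by default) binned on the same grid.  Comparisons use the
probability-mass-per-cell convention on both sides (histogram mass vs
density × cell volume) so the two −ln scales share a normalization.
The relative error between two landscapes is the mean over jointly
valid cells (below the cap in both) of |U_a − U_b| / U_b — the sum of
per-cell ratios divided by the number of cells, so the result reads as
a percentage; the raw (unnormalized) sum is also exposed.  Cells at the
cap carry no density estimate and are excluded.

On the bundled two-gene switch at d = 0.02 this error is 16–25% across
b ∈ [0.4, 0.7] (recomputed by `scripts/acceptance.py`).  The deviation
is a structural property of the closure, not a sampling artifact: a
Gaussian component extrapolates the potential quadratically from the
well, while the true inter-basin potential flattens toward the saddle,
so the mixture overestimates saddle potentials by a factor of 3–4
(the same quadratic-vs-quartic mismatch is exact in the 1D double-well
gradient system).  Barrier *rankings* survive: the per-basin barrier
series of the mixture and simulation landscapes across the b sweep
correlate at r ≈ 0.99.  Conclusions drawn from mixture landscapes
should therefore rest on relative comparisons (which basin is deeper,
how a barrier trends with a parameter), not absolute barrier values.

## Minimum action paths

Transition likelihood under weak noise is governed by the
Freidlin–Wentzell action S = ½∫₀ᵀ ‖ẋ − f(x)‖² dt with endpoints pinned
at two attractors.  Discretization (fixed, so a path's action is
bit-reproducible): K points on a uniform grid with spacing
dt = T/(K−1), forward-difference velocities, drift at segment
midpoints, midpoint-rule quadrature over the K−1 segments.  The
gradient with respect to interior points is assembled analytically from
the drift Jacobian and minimized with L-BFGS-B (projected-gradient
tolerance 1e-6, iteration cap 10⁴), initialized from the straight line
plus (for restarts, default 3) seeded sine-tapered jitter; the lowest
action is kept and non-convergence is flagged on the returned path,
never raised.  Defaults K = 101.

The machinery is validated against the gradient-system identity: for
f = −V′ with V = x⁴/4 − x²/2, the large-T uphill action from x = −1 to
the top at 0 must equal 2·ΔV = 0.5; the solver reproduces this to 0.2%.
Terminal-time scans warm-start each T from the previous minimizer; the
continuum action is non-increasing in T, and the implementation's
monotonicity check allows sub-percent wiggles from the O((T/K)²)
discretization error.  Indirect paths through an intermediate attractor
are two independently minimized legs concatenated at the shared
endpoint and resampled.  Path distance between two K-point paths is the
sum of per-point Euclidean distances divided by the path dimension N
(so distances between paths of different retained dimension are not
directly comparable); paths of unequal K are linearly resampled first.
Per-component min–max normalization (constants map to 0.5) supports
which-gene-moves-first heatmaps.

## Robustness analyses

Parameter perturbation scales every nonzero A/B entry by an independent
uniform factor in a fractional range per sampled set (default
0.75–1.25, 1000 sets for state clustering; 0.95–1.05, 100 sets for path
ensembles; uniform is the minimal assumption for "randomly sampled").
Pooled states are clustered with per-node z-scoring, Euclidean
distance and average linkage; the contract is group recovery at the
requested cluster count, not any particular dendrogram.  Whether to
perturb only A/B or also kinetic constants is a config choice; the
default perturbs the regulation strengths only, matching the
sensitivity analysis below.

Global sensitivity perturbs each nonzero A/B entry one at a time by
±δ (default 10%), re-locates the two endpoint attractors by Newton
polish from the defaults (a root that moves by more than half the
reference norm, loses stability, or disappears flags the record as a
phase change and removes it from the ranking), recomputes both
transition actions at fixed T and K, and scores each link by the
difference of the backward and forward percent changes.

## Synthetic fixtures

The two-gene mutual-inhibition self-activation switch (a = b = 0.5,
S = 0.5, n = 4, k = 1) is the canonical bistable cell-fate motif and
the main test vehicle.  Its diffusion coefficient d = 0.02 was
calibrated once against the switch's reference PC1 contribution rate
(95.8%) and frozen in the fixture; all switch-based analyses reuse it.

The self-activation family (`fixture_self_activation(n)`) provides
n self-activating, all-pairs mutually inhibiting genes with frozen
per-size parameters giving 2, 3, 7, 15 and 22 stable states for
n = 2..6.  With identical parameters the all-to-all motif's state count
is a sum of symmetry-orbit sizes (1, 4, 6, 4, 1 at n = 4), which can
never produce 7; the 4-node member therefore staggers its
self-activation strengths (0.50, 0.51, 0.52, 0.53 at b = 0.22, chosen
at the center of the 7-state plateau b ∈ [0.218, 0.221+]).  A
synthetic two-gene quadrastable variant (strong self-activation
a = 1.2, weak cross-inhibition b = 0.12; attractors both-low, either
single-high, both-high) exercises four-state classification and
perturbation machinery cheaply.

These fixtures emulate multistable Hill-kinetics dynamics with additive
noise.  They do not emulate intrinsic (copy-number) noise,
state-dependent diffusion, parameter heterogeneity across cells, or
unresolved regulators — so passing tests demonstrate correctness of
the pipeline on the model class, not fidelity of any particular
biological network.

## Problem sizes and numerical defaults

Benchmark computations (`scripts/acceptance.py`) use 2000 random starts
for basin weights and, per sweep point, 600 Langevin walkers × 24000
retained records (14.4 million samples) at dt = 0.01 after a burn-in of
200 time units, binned on an 80×80 grid; these sizes leave the
barrier-height estimates' Monte-Carlo error well below the structural
mixture-vs-simulation differences they measure.  Landscape grids
default to 200 points per axis (tests use 64–301), u_cap = 50,
padding 3σ.  All stochastic steps take explicit integer seeds; derived
seeds are small offsets of the user seed.

## Limitations

* The Gaussian closure is trustworthy near attractors and for relative
  comparisons; absolute inter-basin potentials are systematically
  overestimated (see above).  Larger d widens components and the
  closure degrades further; smaller d improves it but makes simulation
  references exponentially slower to converge.
* Attractors within ~2 noise standard deviations of a zero axis make
  the clamped simulation density deviate from the free-Gaussian
  prediction (the low-expression state of the bundled switch at
  d = 0.02 is such a case).
* The minimum action path is computed at fixed terminal time T; the
  T → ∞ limit is approached, not taken (no geometric reformulation).
* Gridded landscapes support 1–3 retained dimensions; union-find
  saddles need the basins resolvable at the chosen resolution.
* No SBML import, no intrinsic-noise (master-equation) dynamics, no
  bifurcation tracking, no limit-cycle systems.
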