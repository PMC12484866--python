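# Methods

This note documents the models implemented in `varimap`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the package's known limitations.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Units and representations

All coordinates and bandwidths are millimeters internally; readers convert
declared units (`um`, `mm`, `m`) on input.  A dataset is a particle measure
`mu = sum_i w_i delta_{x_i} (x) p_i`: positions `x_i` (n, 3), nonnegative
masses `w_i`, and per-particle feature rows `p_i` over an ordered discrete
feature space.  Feature rows may be normalized laws or unnormalized weighted
laws; a flag records which, and the metric uses them exactly as stored —
there is no silent renormalization, because both the resampling objective
and the latent atlas laws work with unnormalized `w_i p_i`.

The varifold inner product is
`<mu, nu> = sum_{ij} w_i u_j K_sigma(x_i, y_j) <p_i, q_j>`, with `K_sigma` a
sum of Gaussians (multiple components support multi-scale matching, e.g.
0.15 mm + 0.75 mm for whole-brain work) and the feature kernel an identity
indicator for labels or the Euclidean inner product for real-valued feature
vectors — computationally the same dot-product reduction.  Quadratic sums
are evaluated exactly by default; an optional cutoff radius (typically
4 sigma) zeroes kernel terms between distant particles for large inputs,
and the truncated value agrees with the exact one to better than 1e-6
relative when the cloud diameter is below the radius.

## Geodesic shooting

Deformations are flows of velocity fields in a Gaussian RKHS `V` with
bandwidth `sigma_V` (the deformation scale).  With particle measures the
flow is finite-dimensional.  Each particle carries a space momentum
`rho^x_i` (3-vector) and a mass momentum `rho^w_i` (scalar); the velocity is

    v(x) = sum_i k(x, x_i) rho^x_i + ((x - x_i)/sigma_V^2) w_i rho^w_i k(x, x_i)

and the state `q = (x, w)` with momenta evolves under `q_dot = dH/drho`,
`rho_dot = -dH/dq`, where `H = (1/2)(sum_i rho^x_i . v(x_i) + w_i rho^w_i
div v(x_i)) = (1/2)|v|_V^2`.  Both momenta are always carried; `rho^w`
drives local expansion/contraction, and the endpoint ratio `w_1/w_0` equals
the Jacobian determinant `|Dphi|` at each particle (set to 1 where
`w_0 = 0`).

Numerics:

- **Integrator** — fixed-step RK4 on [0, 1], default 10 steps.  The
  Hamiltonian is an invariant of the exact flow; measured drift is below
  1e-3 relative at 10 steps on the test geodesics and falls roughly as
  h^4 with refinement, which is the accuracy check the default was set by.
  Non-finite states raise immediately, naming the failing step.
- **Gradients** — `dH/d(x, w, rho)` is implemented in closed form
  (validated against central finite differences to ~1e-9 absolute).  The
  derivative of the endpoint with respect to the initial momenta is the
  discrete adjoint of the RK4 sweep; the required Jacobian-transpose
  products of the Hamiltonian field reduce to Hessian-vector products of H,
  computed by complex-step differentiation of the analytic gradient
  (step 1e-100, exact to machine precision; every kernel expression is
  written complex-analytically, with squared distances as sums of products
  rather than absolute values).  The data-term gradient at the endpoint is
  analytic.  The whole objective gradient therefore costs a small constant
  multiple of one shoot, independent of the particle count's momenta
  dimension.
- **Optimizer** — scipy L-BFGS-B with the exact gradient, default budget
  150 iterations.  A line-search trial that blows up the integrator is
  mapped to a steep finite penalty so the search backtracks instead of
  aborting.  Per-iteration objective values are recorded; the trace is
  monotone non-increasing (asserted in tests).

Matching minimizes `reg * H(q_0, rho_0) + data * ||phi_1 . mu - mu'||^2`
with both weights defaulting to 1 (the relative weight is exposed in the
configuration since no canonical value exists).  For geodesics H equals the
integrated kinetic energy, so penalizing the initial H is the exact
regularizer.  An optional similitude stage is subsumed by the rigid tools
(below) and by the rotation-sweep helper used for the toy problem.

## Cross-modality matching and latent laws

A region-labeled atlas (`pi_i(l)`: membership row per particle, one-hot away
from boundaries) is given one unnormalized law `p_l >= 0` per region over
the target features — the stationarity assumption: one law holds across a
region's spatial extent.  The deformed atlas carries the mixture
`sum_l pi_i(l) p_l` and is matched to the target jointly over momenta and
laws (and the censor bandwidth when censoring is active).  Choices:

- Positivity of `p_l` by exponential reparameterization (`p_l = exp(eta_l)`),
  keeping the optimizer unconstrained and the laws strictly positive.
- The KL prior `J_KL(p_l) = (M_l / sum_f M^T_f) sum_f p_l(f) log(pbar_l(f) |F|)`
  pulls laws toward uniform, weighted by the region's deformed (and
  censored) mass `M_l`, which is recomputed at every objective evaluation;
  its gradient contribution through `M_l` is carried into the adjoint.
- Regions with zero atlas mass are pinned to the uniform law with a warning.
- For fixed geometry the optimal laws solve a nonnegative least-squares
  problem per feature (the loss is quadratic in the laws); this closed form
  backs the rotation-sweep analysis of the toy problem and is tested for
  invariance under feature relabeling.

## Censoring

The support weight is defined in target coordinates.  The planar form is
`alpha(x) = (tanh(<x - a_0, n_0>/lambda) + tanh(<x - a_1, n_1>/lambda))/2`
with anchors on the two bounding planes and inward unit normals: 1 between
the planes, 0.5 on each plane, 0 outside, transition width proportional to
lambda (verified by the 0.25/0.75 crossing distance).  The learned form is a
3→15→5→1 feed-forward network with exponential-linear units whose scalar
output is squashed by `(tanh(z/lambda) + 1)/2`; it handles irregular
(e.g. medial) boundaries.  It is trained as a weighted logistic regression
on interior particles (label 1) against boundary dummies (label 0), class
weight ratio 1000:1 by default to offset the dummies' scarcity (synthetic
tests use balanced classes); training is deterministic for a fixed seed, and
stack ends can be closed by appending dummy copies of the first and last
sections shifted outward by the section spacing.  Training fails loudly if
the weighted accuracy stays below 0.95 on its own training set.

During matching the deformed atlas mass is multiplied by
`alpha(phi(x_i))`, so the loss only sees the measured subvolume; lambda is
optimized jointly (log-parameterized) under
`J_s(lambda) = u ln u + 1 - u`, `u = lambda^2/0.1`, which is convex in
lambda^2 with its unique zero at lambda = sqrt(0.1) mm ≈ 0.32 mm.  This
preferred bandwidth is an absolute length: censoring is meaningful when the
measured support is long compared to ~0.3 mm, which the slab phantom's
brain-scale geometry respects.  Particles mapped outside the support feel no
data force, so their momenta stay near zero and `|Dphi|` stays near 1 — the
contrast the censored-matching test quantifies.

## Scale-space resampling

Approximation at scale sigma minimizes the varifold distance of
`mu_sigma = sum delta_{x~_i} (x) (w~_i p~_i)` to the full measure:

1. **Initialization** — cubic lattice spanning the support with edge
   1.0 x sigma (the proportionality constant is configurable); one particle
   per occupied cube, positioned at a seeded random member, carrying the
   cube's total mass and the uniform law.  Total mass is conserved exactly.
2. **Weights/laws stage** — positions fixed, L-BFGS over the log of the
   weighted laws (200 iterations default, early stop at 1e-7 relative).
3. **Joint stage** — also over positions; displacement statistics are
   reported, and on curvilinear phantoms the particles measurably move onto
   the arc.

The objective is monotone across stages by construction (a stage raising it
is an error).  Total mass after optimization is free, but drifts by under a
few percent on the phantoms — it is measured, not assumed.  Large inputs can
be split along the longest axis and rejoined; desk-scale tests do not need
this.  Baselines at matched particle budget: Lloyd K-means on positions only
(seeded random-subset init, per-cluster feature mass aggregated afterwards —
deliberately blind to features, which is its documented weakness) and
kernel regridding onto the same lattice nodes (per-particle normalized
Gaussian weights; conserves mass exactly).  On the curvilinear-arc phantom
at sigma = 0.1 the optimized scheme's distance is smallest; at scales too
coarse to resolve the arc the lattice itself becomes the bottleneck and the
ordering against K-means can invert, so the comparison is run at a scale
that resolves the geometry.

## Mutual-information feature selection

Detections per section are histogrammed into sigma x sigma squares (default
sigma = 0.05 mm), counts quantile-binned per feature with thresholds
`t_k = inf{t >= 0 | F(t) >= k/q}` from the empirical CDF over occupied
squares only (including empty exterior squares would swamp the quantiles);
q defaults to 10.  The sample space is all (megasquare, square, direction)
triples with megasquares of side 2K (K defaults to 4) enumerated at stride 1
over fully contained placements; each triple yields the half-label
X in {l, r} (vertical split) or {b, t} (horizontal) and the binned count M.
The score is `I(X; M | C)` in natural log (the base only rescales all
scores).  It is exactly zero for constant fields, invariant to monotone
count transforms (rank-based binning) and to transposition, and matches an
exhaustive enumeration oracle to float round-off.  Permutation nulls sit at
the chi-square floor ~(bins/2N) per megasquare, so discrimination improves
with megasquare size.  Ranking is greedy by descending score with
lexicographic tie-break; per-section scores aggregate by summation with
missing features counted as zero.

## Rigid stack alignment

Sections are centered at their mass centroid on load; sections 1 and N are
fixed and each interior section gets (theta_n, tau_n) minimizing the summed
adjacent-pair varifold distances, optimized simultaneously (the objective is
joint) by L-BFGS with analytic gradients.  The identity feature kernel and a
single Gaussian space kernel are used; the default bandwidth is twice the
median nearest-neighbor spacing.  Because sections are centered, a true
perturbation's translation is absorbed on load and the recovered angles
invert the true ones.  Rotation-symmetric sections admit multiple optima;
the phantoms are asymmetric by construction and the optimizer reports the
local optimum from identity initialization.

## Synthetic generators and what they do not show

All generators are pure functions of their parameters and seed.  Phantom
particles carry count-scale unit masses, as aggregated cell or transcript
data do; the data term then dominates the kinetic regularizer the way it
does at realistic masses.  The generators emulate: homogeneous-region
atlas/target pairs (the toy three-region problem, the four-quadrant
law-recovery phantom), known-deformation pairs produced by the package's own
shoot (self-consistency, not an external truth), a half-covered slab with
interior-concentrated deformation, banded vs uniform Poisson gene fields,
thin curvilinear geometry, and rigidly perturbed section stacks.  They do
not emulate: detection noise models of any real technology, segmentation or
cell-typing errors, slice dropout (deliberately not modeled in censoring),
anisotropic section thickness, or feature sets beyond a handful of labels.
Passing tests therefore demonstrate correctness of the estimation machinery
under the stated models, not robustness to real-data artifacts.

## Problem sizes

Matching tests run at 64–144 particles (4^3 grids, 8x8 toy grids, a 90
particle slab), resampling at a few hundred particles, and the toy rotation
sweep at 32 x 32 grids (2048 particles total, 360 angles); these sizes were
chosen so each end-to-end check completes in seconds to about a minute on a
single CPU while keeping every estimate's contrast far from its threshold.

## Known limitations

- O(n^2) kernel sums and O(n^2) shooting per step: intended for reduced
  (resampled) representations of 10^2–10^4 particles, not raw detections.
- The RK4 adjoint stores all stage states; memory grows linearly in step
  count (negligible at desk scale).
- The cross-modality objective is non-convex; recovery results hold from
  identity initialization on phantoms with a dominant basin.  Strongly
  symmetric targets need an external initial rotation (e.g. the sweep).
- NIfTI is the only supported labeled-volume dialect.
- The learned censor's architecture is fixed (3→15→5→1); it delineates
  smooth boundaries, not fine concavities.
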