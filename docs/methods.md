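# Methods

## Model

`coxdeform` fits a hierarchical spatial Cox process to a point pattern
observed on a rectangular study region `G`:

    Y | lambda          ~  PoissonProcess(lambda)
    lambda(s)           =  lambda* . g(mu + beta(s))
    beta | delta, theta, d ~ GP(0, 1/delta, rho_theta)
    d | sigma_d^2, phi  ~  GP_2(identity, sigma_d^2, rho_phi)

The latent field `beta` has exponential correlation measured between the
*deformed* images of two sites,

    Corr(beta(s_i), beta(s_j)) = exp(-||d(s_i) - d(s_j)|| / theta),

where the deformation `d : G -> D` is a bivariate Gaussian process centred
on the identity map with per-axis variances `sigma_d^2 = diag(s11^2, s22^2)`
and exponential cross-site correlation with range `phi`.  Stretching a
subregion in D-space lowers the local correlation of `beta`, so anisotropy
and nonstationarity are learned from the data rather than postulated.

Two link functions are supported.  The probit link `g = Phi` is bounded, so
the maximal intensity `lambda*` is a free parameter with a Gamma prior; the
log link `g = exp` is unbounded and `lambda*` is fixed at 1.

Inference discretizes `G` into an `nx x ny` grid of cells `G_z` with
centroids `s_z` and areas `nu(G_z)`; `beta` and `d` are evaluated at the
centroids and the process likelihood becomes the product of independent
Poisson likelihoods of the per-cell counts `y_z` with means
`lambda* g(mu + beta(s_z)) nu(G_z)`.

Besides the deformation model, two nested baselines share all other
structure:

- **isotropic** — correlation on plain geographic distances (the special
  case `d = identity`, equivalently `sigma_d^2 -> 0`);
- **geometric** — coordinates rotated by an angle `psi in (-90, 90]` and
  the second principal axis divided by a ratio `r >= 1` before measuring
  distances (classical geometric anisotropy, two parameters).

## Identifiability and priors

Distances are invariant under translations/rotations of D-space, so the
deformation is anchored: the first and last centroid (row-major order) are
fixed at their geographic positions.  Anchoring is implemented by
*conditioning* the matrix-normal prior on the two anchor columns rather
than by post-hoc alignment of unconstrained draws: the conditional prior is
again a proper matrix normal (whose mean stays the identity map, because
the anchors sit at the prior mean), which keeps the posterior geometry
smooth for HMC.  A Procrustes repair of unconstrained draws would leave the
sampler wandering along the non-identified manifold.

Default hyperparameters and priors (all config-overridable):

| quantity | default | rationale |
|---|---|---|
| `mu`, `delta` (probit) | fixed 0, 0.5 | `Phi` saturates outside (-3, 3); fixing the location/scale of the latent field identifies `lambda*` |
| `mu`, `delta` (log) | flat improper; Gamma(0.1, 0.1) | standard vague choices for an unbounded link |
| `theta` | Gamma(2, 2/theta0), theta0 = diam(G)/log 20 | prior centred where correlation decays to 0.05 at the region diameter |
| `lambda*` (probit) | Gamma(2, 2/(n/area)) | centred on the empirical mean intensity |
| `sigma_d` | (0.1, 0.1) on the unit square | prior 95% centroid displacement about 0.2 units — local stretches of a few cell widths, which is what modulating the correlation range by small integer factors requires; much smaller scales leave the deformation unable to express useful anisotropy, much larger ones risk folding |
| `phi` | 0.3 | deformation smooth across roughly a third of the region |
| `psi` | uniform on (-90, 90] | no preferred orientation |
| `r - 1` | Gamma(2, 4) | weakly informative, prior mean ratio 1.5 |

`sigma_d` and `phi` are fixed rather than sampled: they trade off
deformation flexibility against folding, and the likelihood is only weakly
informative about them at realistic data sizes.

## Sampling

The posterior is sampled with a dynamic Hamiltonian Monte Carlo sampler
(no-U-turn tree doubling with slice sampling across the trajectory, dual
averaging of the step size towards 80% acceptance, and a diagonal mass
matrix estimated in a warmup window).  Both latent Gaussians use
non-centered parameterizations: `beta = L z` with `L` the Cholesky factor
of its covariance and `z` standard normal, and the free deformation columns
are `identity + sigma_d * (L_cond W)` with `L_cond` the Cholesky factor of
the anchor-conditioned cross-site correlation.  Positive scalars are
sampled on the log scale and the rotation angle through a scaled logistic;
all Jacobians are included.

Gradients are exact, derived by a hand-written adjoint pass: the likelihood
gradient is pulled back through the Cholesky factorization (standard
reverse-mode Cholesky), through the correlation matrix to the pairwise
distance matrix, and through the distances to the deformed coordinates (or
to the rotation/stretch parameters in geometric mode).  The probit Mills
ratio `phi/Phi` is evaluated in log space, so cells deep in the left tail
of the link do not overflow.  Gradients are verified against central finite
differences in the test suite.

Numerical safeguards: every correlation matrix receives a jitter of
`1e-8 x mean diagonal` before factorization (deformed points may nearly
coincide); a Cholesky failure after jitter raises an error that names the
offending matrix and suggests a larger jitter.  Divergent trajectories
(energy error > 1000) are counted and reported; a run report flags
divergence fractions above 5% and split R-hat above 1.05.  ESS and split
R-hat are computed with `arviz`.

A centered parameterization of `beta` is retained as an option purely as a
reference point for sampler-geometry checks.

## Deformation interpolation

The deformation at arbitrary target coordinates is obtained per posterior
draw from the conditional multivariate normal of the joint Gaussian prior
over (targets, centroids), with correlations evaluated on geographic
distances with range `phi`.  The default output is the conditional mean
per draw (what deformation maps summarize); full conditional sampling is a
flag.  A target coinciding with a centroid reproduces the draw's deformed
centroid with zero conditional variance.  Posterior displacement maps
report the mean and SD of `||s_z - d(s_z)||` per cell.

## Model comparison criteria

All criteria act on the per-cell intensity `lambda_z = lambda* g(mu +
beta_z)`; the predictive ones use the per-cell Poisson likelihood of the
observed counts with cell areas included.

- **MAE** — mean absolute error of the posterior mean intensity against the
  known truth (simulation studies only).  The per-cell truth is the
  cell-midpoint value of the generating intensity, matching the
  representative-point convention of the discretization; cell-average
  quadrature is available by flag.
- **IS / AIS** — Winkler interval score of the central 95% posterior
  interval, `(u-l) + (2/alpha) . excursion`, averaged over cells.
- **CPO / slCPO** — per-cell conditional predictive ordinate via the
  harmonic-mean identity over posterior draws, computed on the log scale;
  the `y!` constants are included so lCPO values are proper log predictive
  ordinates.
- **DIC** — posterior mean deviance plus `pD`, with the plug-in deviance at
  the posterior mean of the per-cell linear predictor and the posterior
  means of `lambda*` and `mu` (a plug-in must be chosen; this one is fixed
  and documented).  The same `y!` convention is used in both terms and for
  every model in a comparison, so values are comparable across links.

`compare()` refuses to rank reports computed on different observed counts
(a hash of grid and counts travels with each report).

## Synthetic data

Two generators define the study conditions:

1. **Benchmark intensity** on the unit square: the base surface
   `191 sin(22.8 x^2 (1-y)^2) exp(x^2+(1-y)^2) + 1150` everywhere, plus
   `450 cos(10 y^1.2 (1-x)^1.2)` on the upper triangle `x < y`.  The
   printed source for this surface is typographically ambiguous about the
   placement of the exponential factor; this parse was adopted because it
   reproduces the described behaviour — oscillation that sharpens towards
   two corners, favouring anisotropic modelling — and is used consistently
   throughout.  The `y = x` boundary follows the lower branch (a
   measure-zero convention; the surface is genuinely discontinuous across
   the diagonal under any parse that adds a non-vanishing cosine term on
   one side, so only the convention, not continuity, is testable there).
   Patterns are drawn exactly by Poisson thinning with a bound obtained by
   maximizing over a fine grid and inflating by 5%.
2. **Model-generated patterns** at a known parameter state (known `theta`,
   `lambda*`, deformation): `beta` is drawn from its multivariate normal,
   per-cell counts are Poisson, and events are scattered uniformly within
   cells (exact for a piecewise-constant intensity).  Used for
   parameter-recovery experiments.

What the generators do *not* emulate: irregular (non-rectangular) study
regions, covariate effects, offsets, and continuous-space latent surfaces
(the model itself is discretized, so generator and model share the
piecewise-constant convention).  Passing tests therefore demonstrate
correctness of the inferential machinery and the orderings between model
variants under these conditions, not performance on irregular real-world
regions.

## Problem sizes

Full-length runs of this model (fine grids, 1500–3000 HMC iterations,
several chains) are multi-hour computations.  The packaged test suite and
the acceptance script instead use reduced problem sizes chosen as the
smallest at which each scientific claim is still meaningfully exercised:
benchmark grids of 6x6–15x15 cells, 1–2 chains, and 300–1000 iterations
per chain, with exact-oracle checks (covariance nesting, dense-MVN
interpolation, criteria arithmetic) at toy sizes.  The one-command
`coxdeform benchmark` reproduction defaults to an 8x8 grid and 600
iterations and is config-overridable up to full scale.  Posterior point
estimates at these scales carry visibly wider Monte-Carlo and posterior
uncertainty than full-length runs; quantities that are sums over cells
(slCPO, DIC) also shift systematically with grid resolution, so
comparisons should always be read within a fixed resolution.

## Known limitations

- The deformation map is not constrained to be bijective; strong warps can
  fold.  The prior scale `sigma_d` is the only safeguard (folding repair is
  out of scope).
- Inference is purely discretized; no continuous-space correction is
  attempted.
- The harmonic-mean CPO estimator is noisy for cells that are unlikely
  under most draws; no PSIS smoothing is applied.
- The geometric-anisotropy ratio is bounded below by 1, so its posterior is
  right-skewed; posterior means at coarse resolutions or short chains can
  sit noticeably above the mode.
- D-space dimension is fixed at 2.
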