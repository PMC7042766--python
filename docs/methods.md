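# Methods

This note records the models implemented in `landconn`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Genetic similarity and spatial screening

Individuals are diploid, genotyped at L microsatellite loci; any individual
with a missing locus call or non-finite coordinates is removed before
analysis. The response throughout is the proportion of shared alleles
Dps ∈ [0, 1], computed per pair as the mean over loci of the min-count
allele overlap divided by 2. Dps is symmetric, equals 1 for identical
genotypes, and is invariant to allele relabeling.

Spatial structure is screened with sPCA on the allele-score matrix X
(one 0/1/2 count column per distinct allele per locus, column-centered, not
scaled). The spatial weight matrix W uses a binary distance threshold
(default 300 km, the species' maximum dispersal distance in the motivating
system) with row standardization; individuals with no neighbors keep zero
rows rather than erroring. The sPCA criterion is the eigen-decomposition of
C = Xᵀ((W+Wᵀ)/2)X/n; with W = I it reduces exactly to PCA of X (divisor n).

The global Monte Carlo test uses the **largest positive eigenvalue of C** as
its statistic. The literature's global test is defined only up to the choice
of summary statistic; the largest positive eigenvalue is monotone in cline
strength, cheap, and swappable. The null is built by jointly permuting the
rows of X (genotypes stay intact — alleles are never shuffled across
individuals), with p = (1 + #{perm ≥ obs})/(n_perm + 1). Under a
row-exchangeable null the test is calibrated: its type-I error at α = 0.05
is verified to sit in 0.05 ± 0.03 over 200 null simulations.

Whether allele scores should be rescaled by allele frequency before sPCA is
an open choice; unscaled counts are used here and the statistic's absolute
magnitude is therefore not comparable across panels.

## Covariate layers

Four layers mirror the gene-flow hypotheses: a categorical water/land
barrier (1 = water, 2 = land), percent tree cover (source convention 10–80
with 254 = nonvegetated → 1 and 255 = sparsely vegetated → 5), road density
(total road length within a 1 km circular window divided by the window area,
km/km²), and annual snowfall interpolated from station records by ordinary
kriging with a spherical variogram

γ(h) = nugget + (sill − nugget)(1.5 h/r − 0.5 (h/r)³) for h ≤ r, else sill.

Kriging weights solve the ordinary-kriging system with the unbiasedness
constraint (weights sum to 1, verified to 1e-9), making the predictor exact
at stations when the nugget is 0. Variogram parameters are fitted by
weighted least squares on a 15-bin empirical semivariogram (weights
N(h)/γ²) when not supplied; the bin count and the fit weights are
conventional, not critical.

All layers are block-aggregated onto a common coarse grid before
optimization — mean for continuous layers (nodata ignored), mode for
categorical with ties broken deterministically to the lowest level.
Coordinates are projected meters, row 0 at the north edge; raster I/O is
ESRI ASCII grid, a plain-text format that preserves the affine metadata
without a GIS dependency.

Roads enter as pre-rasterized length-per-cell; a small line rasterizer
exists for the synthetic generator only. No reprojection engine is provided
beyond affine grid alignment.

## Circuit theory

A resistance raster becomes a conductance graph: nodes are unmasked cells;
edge conductance between orthogonal neighbors is the **arithmetic mean of
the two cell conductances** (1/r), and diagonal edges (8-neighbor default)
are divided by √2 to correct path length. Both choices follow common
circuit-raster practice and are switchable.

Effective resistance uses the grounded-Laplacian formulation: one node per
connected component is held at 0 V, the reduced system is factorized once
(sparse LU), and R_ij = G_ii + G_jj − 2G_ij from grounded-inverse columns.
This matches the dense pseudoinverse formula to 1e-8 on random graphs and
satisfies the metric properties of resistance distance. Pairs spanning
disconnected components return an infinite-distance sentinel (not an error)
so bootstrap replicates with isolated samples degrade gracefully; such pairs
are dropped from model fits with a logged count. Samples snap to the nearest
unmasked cell center, ties broken in row-major order.

Per-cell current density for unit injected current is half the sum of
absolute incident edge currents, plus half the injected current at the
terminals (so a uniform single-path chain carries current 1 everywhere).
Kirchhoff residuals are verified below 1e-8.

The omnidirectional map (1) linearly rescales the surface to [1, 100],
(2) places n nodes (default 100) at equal arc-length spacing along the
unmasked cells of the map's outer ring, (3) sums current over all node
pairs, and (4) log-transforms and centers the map to mean 0 over unmasked
cells, so 0 marks average log current density. Perimeter nodes may land on
water cells if the lake touches the map edge; restricting nodes to land is
a one-line alternative but changes the map's interpretation near shorelines.
Pair solves share one factorization (grounded-inverse columns of the
perimeter nodes), so the map costs one sparse solve per node plus cheap
vector work per pair.

## Resistance transformations and optimization

Continuous layers are rescaled to x ∈ [0, 10] and transformed through eight
families built from two base curves — monomolecular f = 1 − exp(−x/s)
(saturating) and Ricker f = (x/s)·exp(1 − x/s) (unimodal, peak at x = s) —
optionally *reversed* (f applied to 10 − x) and/or *inverted* (flipped
vertically: f ← max f − f + min f). The final resistance is
1 + (m − 1)(f − min f)/(max f − min f), so every transform attains exactly
[1, m] on the layer's observed range. Shape s > 0 and magnitude m > 1 are
the optimized unknowns; categorical layers carry one value per level with
the reference (land) fixed at 1 and the water value searched in [1, 2500].
The untransformed "distance only" hypothesis is represented by the IBD
model, not a ninth family.

Composites are cellwise sums of transformed layers shifted to minimum 1
(additive-effects hypothesis). Per-layer contribution is reported as the
range of that layer's transformed values divided by the summed ranges
(×100) — a stated proxy for the optimizer-summary contribution metric used
in the motivating analysis, whose exact definition is not public; the two
need not agree numerically.

The optimizer is a real-coded genetic algorithm: population 25, ≤ 50
generations with early stop after 10 stagnant generations, tournament
selection (k = 3), blend crossover (α = 0.5), Gaussian mutation on log-scale
parameters, categorical family genes mutated by resampling, and elitism (the
returned spec is never worse than generation 0's best). The objective is the
MLPE log-likelihood of similarity against the candidate's effective
resistance (AICc-equivalent at fixed parameter count). All settings are
pinned explicitly for reproducibility and exposed in `GAConfig`.

Identifiability caveat: family labels are not identifiable at small sample
sizes — a Ricker whose fitted peak sits at the domain edge is monotone in
practice, and the wrong-family fit can carry a strictly higher likelihood
than the generating spec. Recovery tests therefore classify the *realized
curve shape* (interior-extremum prominence over [0, 10]) rather than the
label.

## The MLPE mixed model

For pairs (p, q): η = β₀ + β₁·d_pq + u_p + u_q with u_i ~ N(0, σ²_u) iid and
y_pq ~ N(exp(η), σ²_ε). The log link with *additive* Gaussian error is
implemented exactly as stated (mean exp(η), normal residual) — an
exponential-decay model of similarity with distance — rather than the
simpler log-transformed-response model. The shared random effects induce the
MLPE covariance: pairs sharing an individual are positively correlated.

Fitting maximizes the Laplace-approximate marginal likelihood, exact for the
identity link (where the model is a linear mixed model and the fit is
verified against dense GLS and an explicit multivariate-normal likelihood to
1e-4/1e-6). Two profiling steps make each fit cheap enough for GA objective
evaluation and 999-fold replication: the mode of (β, u) is found by
penalized Gauss–Newton with backtracking, and the residual variance is
profiled out analytically, leaving a one-dimensional bounded search over the
variance ratio λ = σ²_u/σ²_ε. Jittered restarts of the inner mode search
(default 3, seeded) guard against poor local modes; fits are deterministic
given inputs and seed.

Conventions: the predictor is standardized (zero mean, unit variance) within
each replicate, so slopes are reported on the standardized scale; n for AICc
is the number of pairs in the replicate (configurable — individuals is the
defensible alternative); k counts fixed effects plus two variance
parameters. R² follows the marginal/conditional decomposition on the link
scale: R²m = σ²_f/(σ²_f + 2σ²_u + σ²_ε,link), R²c adds 2σ²_u to the
numerator, with the residual variance delta-method-mapped to the link scale
(σ²_ε/μ² averaged over pairs). The factor 2 reflects the two independent
individual effects each pair carries.

Under the generating model (β₀, β₁, σ_u, σ_ε) = (−1.0, −0.08, 0.05, 0.02)
with 40 individuals, 200 simulated replicates recover the slope to within
±0.01 on average with a negative sign in ≥ 95% of replicates, and the slope
RMSE shrinks as individuals grow 20 → 40 → 80.

## Replication and consensus

Spatially thinned bootstrap: each of n_sets replicate sets grows by uniform
random draws, accepting a draw only if it is ≥ min_dist (default 100 km)
from every accepted member, until **no eligible individual remains** — every
set is a maximal spaced packing. A rejection-count stopping rule was
considered and discarded: with a budget of 3n consecutive rejections an
individual isolated from all others is missed with probability ≈ e⁻³ per
set, whereas saturation guarantees isolated individuals appear in every set
(the empirically observed behaviour this procedure must reproduce). Failed
or undersized replicate fits receive the worst rank and weight 0 rather than
dropping the replicate, keeping the replicate count fixed.

Within each replicate, models are ranked by AICc (ties share the mean rank)
and weighted by ω_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2). The cross-replicate
consensus is the median ranking under the τ_x rank correlation for tied
rankings (Emond–Mason scoring): the ranking maximizing Σ a_ij C_ij, found by
branch and bound over ordered partitions with an upper bound crediting
decided pairs exactly and undecided pairs with their best achievable
contribution. The search is exact (verified against exhaustive enumeration
of all ordered partitions at m = 4, 5) and capped at 12 models by default.

The panmixia null is the intercept-only MLPE fit; the IBD null regresses on
log geographic distance, consistent with the exponential-decay link.

## Synthetic data: what it emulates and what it does not

The generator mirrors the target study design: ~240 individuals at 14
multi-allelic loci across a ~500 km region with a lake barrier, a smooth
percent-cover field (0–80%), a smooth snowfall field (0–7 m/yr) and sparse
roads. Cover and snow are Gaussian random fields (smoothed white noise,
periodic; correlation length = e⁻¹ correlogram crossing, verified within 20%
of request) mapped through the normal CDF onto their ranges. Allele
frequencies follow softmax logit-clines with random baselines; the logit
scale is pinned so simulated Dps spans ≈ 0.04–0.68, the range typical of
real microsatellite panels (a single clined allele with uniform remainder
produced unrealistic near-0/near-0.8 extremes and was rejected).

Pairwise similarity for fitter- and selection-recovery tests is drawn
directly from the MLPE generative model on the true composite's effective
resistance, deliberately separating "does the estimator work" (exact-model
recovery) from "is the genetic model realistic" (the genotype simulator,
which feeds Dps/sPCA). Consequently the recovery tests say nothing about
model misspecification: real similarities are not exactly
exponential-in-resistance, real fields are not stationary Gaussian, and
mutation/drift dynamics are absent (no coalescent simulation). Clipping of
simulated similarities to (0, 1] is warned above 5%; test settings keep
clipping below 1%.

## Scaling of the validation runs

The motivating full-scale campaign (999 replicates × per-replicate GA
optimization across 8 landscape models ≈ 8,000 GA fits) is a cluster
workload. The package's end-to-end validation runs the same sequence at desk
scale: a 25×25 grid (20 km cells), 30 samples, 99 replicates, and GA
optimization performed **once per model on the full sample** with
per-replicate MLPE refits on the fixed optimized surface.
`RunConfig(ga_per_replicate=True)` restores the per-replicate optimization
when compute allows; results are then replicate-independent surfaces rather
than one surface per model. On known-truth landscapes (barrier + inverse-
Ricker cover vs a wrong-layer competitor, IBD and panmixia) the generating
model attains consensus rank 1 in ≥ 7 of 10 seeded runs; one run takes
~10–15 s on one CPU.

## Numerical choices and degenerate inputs

- Grounded sparse LU with a fixed ground per component; solves are
  deterministic given inputs.
- Constant covariate layers transform to constant resistance 1 with a
  warning (the transform is undefined on a zero range).
- Duplicate station coordinates make the kriging system singular and raise
  an error naming the offending stations.
- Mode aggregation ties break to the lowest category; sample-to-node
  snapping ties break in row-major order; both deterministic.
- The GA encodes shape/magnitude on the log scale, clipping to
  s ∈ [0.1, 10], m ∈ [1.5, 2500], water ∈ [1, 2500].
- MLPE variance-ratio search is bounded to log λ ∈ [−14, 14]; boundary
  estimates (σ²_u → 0) are legitimate degenerate fits, not errors.

## Known limitations

- No REML, and no multi-predictor fixed effects: each candidate model enters
  as a single composite resistance, per the additive-composition design.
- The consensus search is exact only up to the model-set cap (12).
- Perimeter-node placement uses the raster's outer ring; heavily masked
  edges reduce the node count with a warning.
- The contribution metric is a range-share proxy; do not compare its values
  against optimizer-specific summaries from other software.
- ESRI ASCII I/O carries no CRS metadata; the caller owns projection
  bookkeeping (all internal distances are Euclidean in projected meters).
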