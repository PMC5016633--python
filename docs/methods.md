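# Methods

## Demographic models

Growth: for surviving tree *i* of species *j*, relative growth rate is
linear in log diameter, `R_i = r1_j + r2_j ln D1_i` (yr⁻¹), and the observed
second-census log diameter is
`ln D2_i ~ Normal(ln D1_i + R_i (t2_i − t1_i), σ_obs²)`. σ_obs is the SD of
the log-diameter measurement error, shared across trees and applied once per
tree (not per year): it models remeasurement noise, not process noise.
Dead trees carry no growth information and are excluded; species with fewer
than two survivors are dropped with a warning.

Mortality: survival through the interval is
`S_i ~ Bernoulli(exp(−M_i (t2_i − t1_i)))` with log-hazard
`ln M_i = m1_j + m2_j ln D1_i + m3_j D1_i`. The `ln D` term captures the
steep decline of mortality away from the smallest stems, the linear `D` term
lets the hazard turn upward again for large stems (U-shape). Every tree
contributes; species with zero observed deaths are retained and shrunk
toward the community mean by the hierarchy.

Species parameters are exchangeable draws from community-level normals,
`θ_j ~ Normal(μ_θ, τ_θ)`, for θ in {r1, r2, m1, m2, m3}. Priors are weakly
informative and overridable: hypermeans Normal(0, 10²), hyper-SDs
half-Cauchy(2.5), σ_obs half-Cauchy(2.5). There are no individual-level
random effects beyond the observation error: parameters are indexed by
species only.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs, with proposal scales tuned in
50-iteration batches during burn-in toward a 0.44 scalar acceptance rate.
Three design points matter for mixing and are worth recording:

* **Centered/orthogonalized species moves.** `ln D` and `D` are strongly
  collinear over a stand's size range, so raw coordinate updates crawl along
  a likelihood ridge. Species-level proposals move in a per-species
  Gram–Schmidt basis of the features (1, ln D, D), mapped back to the model
  coordinates (a slope update compensates the intercept so the hazard at
  the species' feature center is unchanged). The parameterization of the
  model — and its priors — is untouched; only the proposal directions change.
* **Column translation moves.** A whole species column and its hypermean are
  shifted together; this breaks the slow joint random walk of strongly
  shrunk columns.
* **Deviation rescaling moves.** A column's deviations from its hypermean
  and its hyper-SD are multiplied by a common factor (with the Jacobian and
  species-prior terms collapsing to `+ln c` in the log acceptance ratio);
  this is the classic cure for the hierarchical funnel in weakly identified
  columns such as m3.

Hypermeans are updated by exact conjugate normal draws (a Gibbs step);
hyper-SDs and σ_obs take random-walk steps on the log scale with the
Jacobian included. Growth likelihoods reduce to six per-species sufficient
statistics, making each update O(1) in tree count; mortality likelihoods
are evaluated in one vectorized pass over a flat tree array with per-species
segment sums. Chains start from jittered per-species least-squares /
death-fraction estimates, so independent chains are overdispersed.
Defaults: 3 chains, 20 000 iterations, 10 000 burn-in, thin 10; tests and
examples run much shorter chains, which the diagnostics justify (split
R-hat ≲ 1.01 on growth, ≲ 1.05 on mortality at the sizes used).

Convergence diagnostics (split R-hat, bulk ESS) are computed via arviz;
parameters with R-hat > 1.05 are flagged.

### D95 and rate surfaces

Demographic rates at a reference diameter are deterministic functions of
the draws: `R(D) = r1 + r2 ln D`, `M(D) = exp(m1 + m2 ln D + m3 D)`.
D95 is the 95th percentile of first-census diameters within the
subpopulation `D ≥ 0.1 · Dmax` (the floor suppresses abundance-driven
maxima), with linear interpolation between order statistics (R type-7, the
numpy default) — the same quantile convention used for all credible
intervals.

## Vein metrics

Images are boolean grids (vein = true) with a user-supplied pixel size; the
20× microscope images such metrics are usually computed from do not carry
calibration in the file, so physical units require it explicitly. DA is the
mean over vein pixels of the exact Euclidean distance (between pixel
centers) to the nearest non-vein pixel; DV the mirror image. Chessboard and
city-block transforms are options; Euclidean is the default and matches the
brute-force all-pairs oracle exactly. Out-of-image space is neither vein
nor areole: subsection photographs cut areoles at arbitrary places, so
distances run only to in-image pixels, and an optional border margin can
exclude edge pixels from the averages (default 0).

VLA skeletonizes the mask to 8-connected 1-px centerlines and sums adjacent
skeleton-pixel pairs with weight 1 (orthogonal) or √2 (diagonal); pixel
counting would overestimate diagonal runs by up to 41%. At lattice
crossings the pair-counting rule adds a few diagonal steps per junction, a
bias that vanishes relative to total length as spacing grows against vein
width. VADR is computed per image as that image's DV/DA; an aggregation
helper offers ratio-of-means as an alternative for multi-image species
(one image per species is the expected design).

## Correlation pipeline

Kendall tau is tie-corrected tau-b throughout, with pairwise-complete
deletion of missing values; P-values use exact enumeration for n ≤ 9
without ties, else the normal approximation. The partial correlation is the
closed-form composition
`(τ_xy − τ_xz τ_yz)/√((1−τ_xz²)(1−τ_yz²))`, undefined when either control
correlation is ±1.

Posterior propagation: tau between the trait vector and the rate vector is
computed separately for every posterior draw (vectorized over draws via the
pairwise sign decomposition), giving a posterior distribution of tau whose
equal-tailed 95% interval (type-7 quantiles) decides significance by strict
exclusion of zero. Partial correlations are applied per draw, with the
control covariate fixed and the rate vector varying (a median-rate mode is
available; per-draw is the default because it propagates the posterior into
the partial statistic too). A trait is controlled for Hmax (growth) or WD
(mortality) when its trait–trait correlation with that covariate has
P < 0.05, recomputed from the input data; a trait is never partialled
against itself, and a missing covariate downgrades to no control with a
warning.

Size profiles run over reference diameters 1, 2, 3, … cm, including species
with D95 strictly greater than the reference diameter, and stop at the last
diameter with at least `min_species` (default 20) included.

**A calibration caveat worth knowing.** The "95% interval excludes zero"
rule is not a fixed-level test: its false-positive rate depends on how
informative the data are. For a normal hierarchy with between-species rate
variance s² and posterior variance v, the rate is approximately
`2Φ(−1.96·√(v/(s²−v)))` — near zero when the posterior is diffuse, approaching
one when the posterior is sharp (any nonzero sample correlation then looks
"significant"), and exactly 5% when the posterior carries half the variance
(per-species estimation SE equal to the between-species SD). The null-
calibration check in the acceptance suite therefore constructs its
replicates at that moderately informative design point, where a correct
implementation must reproduce ≈5%; the measured rate is a genuine check of
the uncertainty propagation, not a tautology.

Species-average soil environment maps each stem to the half-open 20 m grid
cell containing its coordinates and averages, unweighted, over a species'
individuals; a stem outside the grid is an error naming the tree.

## Phylogenetic signal

Blomberg's K is computed from the phylogenetic variance–covariance matrix C
(shared root-to-MRCA path lengths): the observed MSE0/MSE ratio — variance
of tip values around the GLS (phylogenetically corrected) mean over the GLS
residual mean square through C⁻¹ — divided by its Brownian-motion
expectation `(tr C − n/(1ᵀC⁻¹1))/(n−1)`. K is invariant to affine
transforms of the trait and to uniform branch rescaling (both tested
exactly). Polytomies are resolved to zero-length bifurcations before
contrast computation.

The Monte Carlo P shuffles trait values across tips. Extremeness follows
picante's convention — the variance of phylogenetically independent
contrasts at or below the observed value — with K itself available as an
alternative statistic, and the add-one estimator
`P = (1 + #extreme)/(1 + n_perm)` so P is never zero. Because the pruning
weights depend only on the tree, the standardized contrasts are a fixed
linear map of tip values, and the whole permutation null is one matrix
product.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
any particular forest: community defaults are RGR ≈ 8%·yr⁻¹ at 1 cm
declining with size (r1 ~ N(0.08, 0.03), r2 ~ N(−0.01, 0.005)), hazard
≈ 2%·yr⁻¹ at 1 cm with a shallow U-shape (m1 ~ N(ln 0.02, 0.5),
m2 ~ N(−0.2, 0.15), m3 ~ N(0.01, 0.01)), log-diameter observation error
σ_obs = 0.02, a 5-yr census interval, and first-census diameters from an
exponential truncated to [1, 50] cm (scale 8 cm), skewed like a real stand
table. Census simulation is the exact forward pass of the model equations;
observation error applies to survivors' second diameters only. Trait tables
attach each trait to a target parameter through a monotone link plus
Gaussian noise and random missingness, so rank associations are controlled
exactly (noise-free monotone links give τ = ±1 by construction). Stem
positions are uniform unless a per-species habitat bias is requested. Soil
fields are Gaussian random fields with a squared-exponential correlogram,
sampled exactly via the kernel's x/y separability (two small 1-D Cholesky
factors); phylogenies are pure-birth (Yule) trees with a final
exponential hold time so tips are not flush with the last split, and traits
evolve by Brownian motion along branches.

What the generators do *not* emulate: real species-abundance distributions,
spatial point patterns (clumping, dispersal limitation), interval-censored
multi-census designs, negative measured growth from trunk damage, or any
particular plot's trait values. Passing tests therefore demonstrate that
the machinery is correct under the stated model, not that the model fits
any real forest.

Reproducibility: every generator takes one root seed and draws from a fixed
per-generator substream, so adding a generator never perturbs another's
output; identical seeds give identical outputs byte for byte.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 50 random images ≤ 64×64
for the distance-metric oracle; 20 replicate growth fits of 20 species ×
200 trees at 2 chains × 2500 iterations; one mortality fit of 5000 trees at
2 chains × 3000 iterations; 1000 random tied vectors for the tau oracle;
400 null replicates of 40 species × 400 draws for the significance-rate
calibration; 500 Brownian traits on a 50-tip tree and 200 null permutation
tests (199 permutations each) for K. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full run in a
few minutes on one CPU.

## Known limitations

* The mortality posterior mixes more slowly than growth (rare deaths,
  collinear size terms); short chains can flag R-hat on m3-related
  parameters. The moves described above make default-length chains clean.
* The tau significance rule inherits the calibration caveat above; treat
  profile significance as descriptive, not as a fixed-level test.
* Skeleton-based VLA carries a small positive junction bias on dense
  lattices.
* Exact P-values for tau are only used for n ≤ 9 without ties; elsewhere the
  normal approximation is standard but approximate at small n.
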