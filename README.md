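# veindemog

Tools for asking whether the architecture of a leaf's vein network predicts
how fast a tree grows and how likely it is to die — and how those
associations change with tree size — in fully mapped, repeatedly censused
forest plots.

The package implements, as a tested reusable pipeline on synthetic data with
known ground truth:

* **Vein-image metrics** (`veinmetrics`): from a binary image (white veins on
  black lamina), vein length per unit area (VLA, mm·mm⁻², via skeletonized
  centerlines with √2-weighted diagonal steps), the mean distance from vein
  pixels to the nearest non-vein pixel (DA, a vein-width proxy), the mean
  distance from areole pixels to the nearest vein pixel (DV, an areole-size
  proxy), and their ratio VADR = DV/DA. Distances are exact Euclidean
  transforms between pixel centers.
* **Hierarchical Bayesian demography** (`demogfit`): relative growth rate
  linear in log stem diameter, `R_i = r1_j + r2_j ln D1_i` with
  `ln D2 = ln D1 + R_i Δt` and Gaussian observation error on the log scale;
  survival Bernoulli with `p_i = exp(−M_i Δt)` and log-hazard
  `ln M_i = m1_j + m2_j ln D1_i + m3_j D1_i`. Species parameters are drawn
  from community-level normal distributions; posteriors come from a
  hand-written adaptive Metropolis-within-Gibbs sampler with convergence
  diagnostics (split R-hat, ESS).
* **Posterior-propagated rank correlations** (`corrpipe`): Kendall tau-b
  between a species trait and the *posterior distribution* of a demographic
  rate at reference diameters 1, 2, 3, … cm, computed per posterior draw;
  significance when the 95% interval of tau excludes zero; Kendall partial
  correlations removing maximum height (for growth) or wood density (for
  mortality); species entry into each size class governed by D95, the 95th
  percentile diameter of the large-stem subpopulation (D ≥ 10% of the
  species maximum); trait–trait and trait–soil matrices; species-average
  soil environment from gridded maps; large-statured subsets.
* **Phylogenetic signal** (`phylosignal`): Blomberg's K with a
  tip-randomization Monte Carlo P-value (extremeness judged by the variance
  of phylogenetically independent contrasts).
* **Synthetic data** (`synthgen`): every input above with known ground
  truth — parameter tables, two-census tree tables simulated through the
  exact model equations, trait tables with tunable rank links to demography,
  lattice vein images with analytic geometry, Yule phylogenies with
  Brownian-motion traits, and Gaussian-random-field soil grids.

The library is used from Python; `veindemog.io` reads and writes all inputs
and outputs as plain CSV/Newick, and `examples/` has one short script per
capability.

## Worked example

Fit both demographic models to a simulated 10-species census and read off
rates at a 1-cm reference diameter (`examples/fit_demography.py`):

```
growth: max R-hat 1.011, min bulk ESS 460, 0 flagged
mortality: max R-hat 1.008, min bulk ESS 172, 0 flagged

species   RGR(1cm) median [true r1]    M(1cm) median [true exp(m1)]
sp001   0.0401  [0.0410]          0.0206  [0.0306]
sp002   0.0827  [0.0822]          0.0204  [0.0224]
sp003   0.0876  [0.0876]          0.0232  [0.0192]
```

RGR(1 cm) equals the species intercept r1 because ln 1 = 0; the posterior
medians sit close to the bracketed simulation truths, with hierarchical
shrinkage visible in the rarely observed mortality rates. R-hat near 1 and
healthy effective sample sizes say the chains mixed.

Running the correlation pipeline on a community where vein density was
simulated with a positive rank link to growth
(`examples/trait_rate_profiles.py`) gives a tau profile along stem diameter:

```
 ref_d  median_tau     q025     q975  n_species  significant control
   1.0    0.799584 0.784293 0.810105         30         True    Hmax
   2.0    0.767819 0.753149 0.777970         30         True    Hmax
```

Each row summarizes the posterior distribution of Kendall's tau between the
trait and the growth rate at that diameter; `significant` means the 95%
interval excludes zero, and `control` names the covariate partialled out
(here maximum height, because the simulated trait also correlates with it).

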