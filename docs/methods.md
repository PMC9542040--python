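# Methods

## The model

`phylocrit` models critical oxygen tension (Pcrit, kPa) of fishes as a
phylogenetic multilevel (mixed) regression. For measurement record *i* of
species *s(i)*:

```
y_i = x_i' β + a_{s(i)} + u_{s(i)} + ε_i
a ~ MVN(0, σ²_phylo · C)        phylogenetically structured species intercepts
u ~ MVN(0, σ²_species · I)      unstructured species intercepts
ε_i ~ N(0, σ²_resid)            record-level residual
```

The response is left untransformed on the kPa scale, so coefficients read as
kPa per covariate unit. The final fixed-effect structure is: intercept,
measurement temperature *T*, log10 genome size (GS, a cell-size proxy),
log10 body mass (BM), salinity (PSU), residual metabolic rate, and the
*T*×GS and *T*×BM interactions. A larger candidate set (percent of maximum
body mass with quadratic and temperature-interaction terms, relative
acclimation temperature, respirometry method, maximum body mass substituted
for genome size) is available for model comparison; respirometry is
dummy-coded against intermittent-flow as the reference.

`C` is the Brownian-motion correlation matrix implied by the phylogeny after
Grafen branch-length assignment and rho rescaling (below). Because `C` has a
unit diagonal, `σ²_phylo` is directly the phylogenetic variance on the trait
scale, and the two species-level variances are identified on a common scale;
this coupling is asserted at run time.

### Priors

The published analysis states only that priors were weakly informative
Gaussians. We use N(0, 10²) per fixed-effect coefficient on the natural
covariate scales and half-N(0, 5) on each standard deviation; both scales
are configuration fields of `ModelSpec`. Covariates are not centered or
scaled, keeping coefficients directly comparable with the published
posterior table. With unscaled covariates the prior is mildly informative
for the genome-size main effect (posterior mean ≈ −7.5), which is one
reason exact reproduction of published point estimates is expected only to
about one decimal place.

## Sampling: collapsed Gaussian sampler

Every conditional distribution in this model is Gaussian, so the fit does
not need a general-purpose gradient sampler:

1. β, a and u are integrated out analytically. The marginal over the 1–3
   log standard deviations is sampled by an adaptive random-walk Metropolis
   chain (Haario-style covariance adaptation during warmup, Robbins–Monro
   tuning toward ~30% acceptance, proposal frozen afterwards).
2. For each kept draw of (σ_phylo, σ_species, σ_resid), β | σ, y is drawn
   from its exact Gaussian conditional, then (a, u) | β, σ, y from theirs.

The result is an exact sample of the joint posterior; the only
autocorrelation lives in the low-dimensional σ block, and the β draws are
nearly independent (effective sample sizes close to the draw count).
Convergence is monitored per parameter by split-R̂; any value above 1.01
flags the fit as non-converged — the posterior is still returned, with a
warning, never silently discarded. Defaults are 3 chains × 15,000
iterations with 7,500 warmup (22,500 post-warmup draws); model selection
uses a lighter 2 × 4,000 / 1,000 setting and the winning model is refit at
full settings.

Each Metropolis step costs one Cholesky factorization of an n×n covariance,
and each kept draw one more — about 8 ms at n = 600 — so a full-size fit
with the light setting completes in well under a minute, and the default
setting in minutes.

Per-record log-likelihood contributions are stored as the conditional
normals N(y_i | x_i'β + a + u, σ²_resid); these feed PSIS-LOO.

## Tree handling

Input Newick branch lengths are discarded. Node heights follow Grafen:
height ∝ (number of descendant tips − 1), normalized so tips sit at 0 and
the root at 1 (normalization makes the phylogenetic variance identifiable on
the same scale as the species variance). Heights are then power-transformed,
h ← h^ρ with ρ = 0.4 by default; ρ < 1 raises internal nodes and stretches
the branches near the tips, giving recent divergence more weight. The
normalize-then-power order matches standard comparative-methods
implementations; the original report does not state the order, so it is a
documented convention here (a `rho_profile` utility refits the model on a
ρ grid and reports LOO per value for sensitivity analysis). Polytomies are
retained — descendant-tip counting needs no bifurcation. The correlation of
two tips is the shared root-to-MRCA path length, 1 − h(MRCA), computed in
one postorder sweep.

## Oxygen physics

Pcrit readings arrive in kPa, mmHg, percent air saturation, mg/L or μmol/L.
Pressure units convert by constant ratio. Percent air saturation uses
pO2 = (pct/100) × 0.2095 × (P − p_vapor(T)), with the saturation vapor
pressure of water from the Arden Buck equation. Concentration units convert
by Henry-law proportionality against the saturation concentration, which is
the Garcia & Gordon (1992) combined fit of the Benson–Krause data — the
de-facto standard in respirometry tools. We use their per-liter (cm³/dm³)
coefficient set converted to μmol/L (44.6596 μmol per mL O2 at STP), since
the concentration inputs are per liter of water; at 35 PSU this differs by
~2.5% from the per-kilogram fit. Non-standard atmospheric pressure scales
the saturation concentration by the dry-air fraction. The solubility
function is a single swap point should a different formulation be needed.

Factorial aerobic scope uses the printed formula exactly: FAS = 21/Pcrit
with Pcrit clipped below at 2 kPa, capping FAS at 10.5. The numerator is the
nominal 21 kPa, not a humidity- or pressure-corrected pO2. The projection
utility (`project_fas_grid`) evaluates the linear predictor at posterior-mean
fixed effects with random effects at zero — a posterior-predictive variant
would be straightforward but the mean is the documented default — for a
user-supplied temperature grid, salinity 0 (fresh) or 35 PSU (marine), and
fixed body mass and genome size; grid cells outside the fitted temperature
range are flagged as extrapolations.

## Residual metabolic rate

log10 whole-organism metabolic rate (μmol O2/h) is regressed by OLS on
salinity, measurement temperature and log10 body mass over the records with
an observed rate (record-level by default; a species-means option exists
because the original analysis does not state the level). A record's residual
— observed minus expected — enters the Pcrit model as a covariate; records
without a rate get residual 0 and carry an imputation flag so a sensitivity
refit excluding them is one switch.

## Model comparison and variance decomposition

PSIS-LOO is computed from the stored pointwise conditional log-likelihoods
(generalized-Pareto smoothing of the upper importance-ratio tail; per-record
k̂ > 0.7 logged, not corrected). Model weights are pseudo-Bayesian model
averaging, w_m ∝ exp(elpd_m − max elpd) — the simplest scheme consistent
with assigning each candidate a probability; it is computed from the
LooResult objects so a stacking scheme can be swapped in.

The variance partition follows Gelman-style finite-population logic for the
fixed part: per posterior draw, V_fix is the sample variance of Xβ over the
records, and the three scale parameters contribute their σ². Fractions are
each component over the sum; means are reported with medians alongside
(the published fractions do not state which). Phylogenetic heritability
conditions on the fixed effects: λ = σ²_phylo/(σ²_phylo + σ²_species +
σ²_resid). A supplementary diagnostic reports the per-draw R² between the
fitted fixed-effect values and the phylogenetic effect (the "shared"
variance overlap).

## Synthetic data and what passing tests show

The generator simulates a pure-birth species tree, species traits and
record covariates, then produces responses from the model's own generative
process. Defaults are the published posterior means — β = (5.56, −0.03,
−7.47, −1.37, 0.08, 2.20, 0.44, 0.06) for (intercept, T, GS, BM, salinity,
residual MR, T×GS, T×BM), σ_phylo = 2.22, σ_species = 1.02 — with
σ_resid = 1.67 chosen so the implied heritability is λ ≈ 0.56, matching the
published estimate; σ_resid is thus a derived default, not a published
value. Covariate distributions emulate reported ranges: T ~ U(5, 32) °C
(bracketing the 15/28 °C quartiles), log10 mass ~ N(0.8, 0.8) g, log10
genome size ~ N(0, 0.25) pg, half the species freshwater (salinity 0) and
half marine (30–36 PSU), species residual metabolism ~ N(0, 0.15).
Metabolic rates are generated from a plausible allometric baseline plane
(intercept 0.2, salinity −0.002, temperature 0.02, log-mass 0.88 on the
log10 scale, record noise SD 0.1) plus the species residual, so the baseline
regression can recover the residual covariate; 20% of records lack a rate.
Acclimation temperature equals measurement temperature (as for most real
records), so the relative-acclimation covariate is exercised only by the
I/O layer and candidate specs, not by the generator.

What this does *not* emulate: Pcrit measurement error from respirometry
traces, non-Gaussian residuals, unbalanced phylogenetic sampling of real
clades, correlated covariates (e.g. mass–genome size), or missingness that
depends on the trait. Passing recovery tests therefore demonstrates the
estimator is correct for the model's own data-generating process at study
scale — not that the model is adequate for any particular real dataset.

### Recovery targets

For a single simulated dataset, the realized variance of one correlated
MVN draw of 170 species effects deviates substantially from its generating
σ² (realized SD of the phylogenetic effects ranges roughly 1.5–2.7 around a
generating 2.22 across seeds). A fit can only see the realization, so
recovery of the variance decomposition is assessed against the *realized*
generating fractions of the dataset in hand (computed from the stored
generating draws of a, u and ε); the theoretical σ²-based fractions are also
available. Coefficient recovery is assessed as coverage across replicates,
where the theoretical/realized distinction does not arise.

## Problem sizes and numerical choices

Test and example runs use reduced sizes chosen as the package's own
verification scale: oracle comparisons on toys (≤ 20 records for dense-MVN
equivalence, ≤ 12 tips for tree oracles, n = 30 for refit-LOO), coverage
over 20 replicates at 60 species / 300 records with 2 × 1,000/400 chains,
and single-dataset checks at the study's 600 records / 170 species with
2 × 1,500/500 chains. Degenerate inputs: a non-positive-definite covariance
evaluates to zero likelihood (the proposal is rejected); log-σ proposals are
bounded to [−14, 12]; Cholesky of the correlation matrix in the generator
adds 1e-10 jitter; ties in KDE-based p(MAP) are resolved by evaluating the
density on a 512-point grid over the draw range. p(MAP) is the kernel
density at zero over the density at the posterior mode, reported for fixed
effects only, as in the published table.

## Known limitations

- The split between the phylogenetic and the unstructured species variance
  is identified only through the tree's off-diagonal correlations (mean
  ≈ 0.19 for a 170-tip Grafen/ρ = 0.4 tree). On a single dataset the
  posterior can reallocate a realization's unstructured variance to the
  phylogenetic term (or vice versa) while remaining perfectly calibrated —
  the generating value stays inside the credible interval, but point
  estimates of heritability can be off by about ±0.1. The sum of the two
  components, and the full four-way fractions, recover much more tightly.
- The Metropolis σ block mixes more slowly than the conditional β draws;
  short chains can trip the split-R̂ < 1.01 flag on the variance components
  while the fixed effects are already well resolved. The flag is
  informative, not fatal, and disappears at the default chain lengths.
- Exact reproduction of the published coefficient table requires the
  deposited dataset and the original (unstated) prior scales; with the
  deposited data one should expect agreement to about one decimal place.
- The FAS projection uses posterior means, so its uncertainty is not
  propagated.
- `p(MAP)` uses a Gaussian KDE; for extremely skewed posteriors the density
  ratio is approximate.
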