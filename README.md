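# phylocrit

Bayesian phylogenetic multilevel analysis of fish hypoxia tolerance.

Hypoxia tolerance of a fish is measured as its critical oxygen tension
**Pcrit** — the lowest ambient O2 partial pressure at which it still
sustains its standard metabolic rate; lower Pcrit means more tolerant.
`phylocrit` is for comparative physiologists who want to ask, across many
species and hundreds of respirometry records, how Pcrit depends on
temperature, body mass, cell size (via genome size), salinity and residual
metabolic rate, while accounting for shared evolutionary history.

The core model, for record *i* of species *s(i)*:

```
Pcrit_i = x_i'β + a_s(i) + u_s(i) + ε_i
a ~ MVN(0, σ²_phylo C)      phylogenetically structured species intercepts
u ~ MVN(0, σ²_species I)    unstructured species intercepts
ε_i ~ N(0, σ²_resid)
```

with fixed effects x'β = intercept + T + log10 GS + log10 BM + salinity +
residual MR + T×GS + T×BM, and C the Brownian correlation matrix of the
phylogeny after Grafen branch lengths and rho rescaling (ρ = 0.4). The
temperature interactions are the scientific point: they let the effect of
body and cell size on hypoxia tolerance reverse between cold and warm
water. Downstream quantities: PSIS-LOO model weights over a candidate set,
a variance decomposition (marginal / phylogenetic / species / residual),
phylogenetic heritability λ = σ²_phylo/(σ²_phylo+σ²_species+σ²_resid), and
a projection of factorial aerobic scope, FAS = 21/Pcrit (Pcrit floored at
2 kPa, capping FAS at 10.5), over temperature grids.

Every stage is verifiable without the original study data: the `synth`
module generates datasets from the model's own generative process with
known truth (defaulting to the published coefficient set), and the test
suite checks the pipeline by parameter recovery and by brute-force oracles.
See `docs/methods.md` for the modelling details and design decisions.

## Worked example

Simulate a study-like dataset (300 records, 60 species) from the published
coefficients, refit it, and project aerobic scope:

```python
import numpy as np
from phylocrit import synth, model, decomp, oxygen

truth = synth.default_truth(seed=1)
records, traits, C, truth = synth.simulate_dataset(truth, 300, n_species=60)
post = model.fit(records, truth.spec(), C=C,
                 mcmc=model.MCMCConfig(chains=2, iterations=2000, warmup=700), seed=42)
print(model.summarize(post).round(3))

lam = decomp.heritability(post)
print(f"phylogenetic heritability: {lam['mean']:.2f} [{lam['q2.5']:.2f}, {lam['q97.5']:.2f}]")

for t in (10.0, 28.0):
    pcrit, fas, _ = oxygen.project_fas_grid([t], "marine", np.log10(1000.0), np.log10(4.0), post)
    print(f"1000 g, 4 pg marine fish at {t:>4} degC: Pcrit {pcrit[0]:5.2f} kPa -> FAS {fas[0]:.2f}")
```

Output:

```
             mean   q2.5  q97.5  effective_sampling  p_map
parameter
sd_phylo    1.632  0.504  2.846              72.628    NaN
sd_species  1.247  0.483  1.920              85.744    NaN
sd_resid    1.701  1.551  1.878             147.869    NaN
intercept   4.008  2.262  5.792            2662.930  0.001
temp       -0.029 -0.067  0.007            2310.069  0.305
gs         -6.071 -9.361 -2.820            2629.916  0.002
bm         -1.496 -2.181 -0.819            2612.323  0.000
salinity    0.081  0.051  0.111            2556.207  0.000
resid_mr    3.030 -0.086  5.979            1843.565  0.149
temp:gs     0.333  0.212  0.459            2576.089  0.000
temp:bm     0.061  0.027  0.095            2558.771  0.003

phylogenetic heritability: 0.37 [0.04, 0.70]

1000 g, 4 pg marine fish at 10.0 degC: Pcrit  2.23 kPa -> FAS 9.42
1000 g, 4 pg marine fish at 28.0 degC: Pcrit  8.59 kPa -> FAS 2.44
```

Reading it: every generating coefficient (e.g. salinity 0.08, T×GS 0.44,
T×BM 0.06) sits inside its 95% interval; the main temperature effect is
weak on its own (p(MAP) 0.31) because temperature acts through the
interactions; and the same large-bodied, large-genome fish that is
comfortable at 10 °C (FAS 9.4) is down to FAS 2.4 at 28 °C — the
temperature-dependent size effect the model is built to expose. At this
reduced size the species-level variance split is wide (heritability
0.37 [0.04, 0.70]); it tightens at the full 600-record scale. The
`sd_*` rows mix more slowly than the coefficients (they are the only
parameters sampled by Metropolis rather than drawn exactly), which the
effective-sampling column makes visible.

The same pipeline is scriptable from the shell (`phylocrit simulate`,
`clean`, `baseline`, `tree`, `fit`, `compare`, `decompose`, `fas`,
`project`); run `phylocrit --help`.

## Real data

`phylocrit clean` expects a measurement CSV with columns
`species, pcrit, pcrit_unit, temp_meas, temp_acclim, salinity, body_mass_g,
metabolic_rate, mr_unit, respirometry, source_id` (a `column_map` can adapt
other headers), a trait CSV with `species, genome_size_pg, max_body_mass_g`,
and a Newick tree covering the species. Pcrit units may be kPa, mmHg,
percent air saturation, mg/L or μmol/L; conversions account for temperature
and salinity via Garcia & Gordon (1992) solubility, and the token
`seawater` maps to 35 PSU.

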