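# msom — hierarchical multi-species occupancy modelling

`msom` estimates how land use and land cover shape the occupancy of whole
vertebrate communities from detection/non-detection surveys, while
correcting for imperfect detection.  It is written for ecologists analysing
repeat-survey data (camera traps, point counts, transects, quadrats) across
a set of sites: detection histories and covariate tables go in; community
and species-level effect estimates, goodness-of-fit diagnostics, and
detection-corrected species richness come out.

## The model

For species *i* at site *j* on survey occasion *k*:

```
z(i,j)   ~ Bernoulli(ψ_ij)            latent occupancy
x(i,j,k) ~ Bernoulli(p_ijk · z(i,j))  detection given presence

logit(ψ_ij)  = u_i + α1_i·elevation_j + α2_i·forest_j + α3_i·anthropogenic_j
logit(p_ijk) = v_i + β1_i·date_jk + β2_i·time_jk + …
```

Covariates are standardized; the detection covariate set is configurable
per dataset.  Species-level coefficients share community
hyper-distributions — e.g. `α2_i ~ Normal(μ_α2, σ_α2)` — so rarely detected
species borrow strength from the community.  Hyper-means get weakly
informative `Normal(0, 2.25)` priors on the logit scale, hyper-sds
`Uniform(0, 5)`.

Inference is a purpose-built Metropolis-within-Gibbs sampler with exact
data augmentation: `z` is drawn from its closed-form Bernoulli full
conditional (forced to 1 wherever the species was detected), hyper-means
are conjugate Normal updates, and coefficients and log hyper-sds move by
adaptive random-walk Metropolis (Robbins–Monro tuning to 0.44 acceptance,
frozen at the end of burn-in).  The per-iteration sweep is numba-compiled;
runs are bit-reproducible from a single base seed.

Also included: covariate preparation (standardization, pooling of seven
land-cover classes into forest / degraded forest / anthropogenic habitat,
correlation + VIF collinearity screening with |r| ≤ 0.60 and VIF ≤ 3),
split-chain rank-normalized R-hat, a posterior-predictive chi-square
Bayesian p-value (lack of fit outside 0.05–0.95), effect-strength
classification from credible intervals (strong / moderate / weak), richness
prediction over covariate grids, and a synthetic-community generator with
preset scenarios at the community effect sizes reported for the Mumbai
Metropolitan Region vertebrate study (`mmr_mammals`, `mmr_birds`,
`mmr_amphibians`, `mmr_reptiles`, `null`).

## Worked example

Simulate a mammal-like community at the preset effect sizes (25 species,
35 sites, 6 occasions), refit it, and summarize:

```python
import msom

scenario = msom.preset_scenario("mmr_mammals")
data, truth = msom.simulate_community(scenario, n_species=25, n_sites=35,
                                      n_occasions=6, seed=42)

cfg = msom.McmcConfig(chains=3, iterations=15_000, burn_in=5_000, thin=10,
                      base_seed=1)
samples = msom.run_mcmc(data, truth.site_covs, truth.occasion_covs,
                        scenario.model_spec, cfg)

print(msom.hyper_summary(samples).head(5).round(3).to_string(index=False))
gof = msom.bayesian_p_value(samples, data, truth.site_covs,
                            truth.occasion_covs, seed=1)
print("Bayesian p-value:", round(gof.bayes_p, 3))
print(msom.estimated_richness(samples, data).head(3).round(2).to_string(index=False))
```

Output (the 980-detection dataset of seed 42; max R-hat 1.005 across the
3000 retained draws):

```
                    parameter   mean  ci_low  ci_high
                         mu_u -0.090  -0.634    0.432
                         mu_v -0.790  -1.115   -0.484
          mu_alpha[elevation] -0.564  -1.050   -0.124
       mu_alpha[forest_cover]  2.197   1.595    2.887
mu_alpha[anthropogenic_cover] -1.907  -2.518   -1.380
Bayesian p-value: 0.732
  site  observed  posterior_mean  ci_low  ci_high
site01         6            6.20     6.0      7.0
site02        11           13.94    11.0     17.0
site03        15           19.11    17.0     21.0
```

The community hyper-means recover the simulation truths (elevation −0.404,
forest +2.404, anthropogenic −1.812) within their credible intervals: a
strong positive forest effect, a strong negative anthropogenic effect.
The Bayesian p-value sits comfortably inside (0.05, 0.95) — no lack of fit
— and the detection-corrected richness at each site is at least the
observed count, with the gap widening where detection probability is low.

The same pipeline runs from the shell:

```sh
msom simulate --preset mmr_mammals --species 25 --seed 42 --out-dir sim/
msom fit --detections sim/detections.csv --manifest sim/manifest_occasions.csv \
         --site-covs sim/site_covariates.csv --occ-covs sim/occasion_covariates.csv \
         --config sim/model.yaml --iters 15000 --burnin 5000 --thin 10 \
         --seed 1 --out-dir fit/
msom summarize --fit-dir fit/ --out hyper.csv
```

or end-to-end from a YAML config with `msom run config.yaml` (exit code 2
for missing inputs, 3 for invalid configuration; non-convergence warns and
flags the run manifest rather than failing).

Field data enter as delimited text: long-format detection records
(`species,site,occasion,detected`) with an occasion manifest marking which
(site, occasion) cells were surveyed, plus site-level and occasion-level
covariate CSVs.  A spreadsheet shim (`read_supplementary_workbook`) imports
detection histories from workbooks in the same long layout.

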