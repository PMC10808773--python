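# pinebird

Bayesian analysis of **paired point-count and passive-acoustic bird
surveys**, built for the study design used to relate Clark's nutcracker
(*Nucifraga columbiana*) habitat use to whitebark pine (*Pinus
albicaulis*) stand characteristics: ~30 inventory sites clustered in
~10 drainages, three harvest seasons, 0-3 point counts per site-season,
and automated recording units logging daily vocalization counts.

Two models are fit in parallel, giving independent lines of evidence
about the same habitat covariates:

1. **Spatially explicit multi-season occupancy model** for the point
   counts. Latent occupancy `z_jt ~ Bernoulli(psi_jt)` with
   `logit(psi_jt) = x_jt' beta + w_j`, imperfect detection
   `y_jtk ~ Bernoulli(p_jtk * z_jt)` with `logit(p_jtk) = v_jtk' alpha`,
   and a site-level spatial random effect `w` from a Nearest-Neighbor
   Gaussian Process (15 neighbors, exponential covariance
   `sigma^2 exp(-phi d)`). Fit by Polya-Gamma Gibbs sampling with an
   informative uniform prior on the spatial decay expressed through the
   *effective spatial range* `3/phi` (default support 4.36-84.31 km).
2. **Negative-binomial GLMM** for daily vocalization counts (relative
   activity): `log(mu) = x' beta + u0_g + u1_g DATE + u2_g DATE^2` with
   group-level random intercept and date slopes, overdispersion
   `Var = mu + mu^2/kappa`.

Around them: Freeman-Tukey / Chi-squared posterior predictive checks
under two data groupings, the 95% coverage rate, split-chain Rhat and
autocorrelation ESS, probability-of-direction summaries,
precision/recall scoring of an automated call detector, a synthetic-data
generator that draws from exactly these hierarchies, and a CLI.

See `docs/methods.md` for the full model and sampler documentation.

## Worked example

Simulate a paired survey bundle with known truth, then run the whole
pipeline (short chains here; defaults are 3 x 60,000):

```bash
pinebird simulate --out-dir demo --seed 1
cat > demo/config.yaml <<EOF
sites: demo/sites.csv
covariates: demo/covariates.csv
surveys: demo/surveys.csv
vocals: demo/vocals.csv
annotations: demo/annotations.csv
out_dir: demo/results
seed: 1
occ_iter: 6000
occ_burn: 3000
occ_thin: 3
glmm_iter: 6000
glmm_burn: 3000
glmm_thin: 3
EOF
pinebird run --config demo/config.yaml
```

which prints the cross-model comparison of the shared covariates
(posterior mean, 95% CI and probability of a positive effect per model,
plus whether the two models agree on the sign):

```
    covariate          model      mean      q2.5     q97.5  prob_positive  sign_agreement
 cone_density      occupancy  0.702640 -1.205845  2.916980       0.718667            True
 cone_density vocal_activity  0.464192  0.424595  0.505570       1.000000            True
  mean_dbh_cm      occupancy  1.868989  0.274400  3.808877       0.994667            True
  mean_dbh_cm vocal_activity  0.132887  0.088229  0.176389       1.000000            True
prop_infected      occupancy -0.528255 -2.176461  0.662161       0.218667           False
prop_infected vocal_activity  0.124690  0.070209  0.175739       1.000000           False
         year      occupancy -1.331775 -2.861586  0.055551       0.029667            True
         year vocal_activity -0.160323 -0.200927 -0.118604       0.000000            True
outputs in demo/results
```

Both models recover the generating structure where the data are
informative: positive cone and DBH effects (occupancy effects on the
logit scale, activity effects on the log scale; the 270-visit occupancy
data are far less precise than the ~5,800 daily counts, hence the wide
occupancy intervals), and a negative year trend. The weak infection
effect illustrates why the sign-agreement flag matters: the two data
streams disagree on the sign of an effect whose occupancy CI straddles
zero. `demo/results/` also contains posterior draws and
summaries for every parameter (`occupancy_summary.csv`,
`glmm_summary.csv`), Bayesian p-values (`checks.csv`), Rhat/ESS with
pass flags (`convergence.csv`), per-site-per-year occupancy and
activity predictions, and the detector metrics (the simulated detector
has precision 1.0 and recall ~0.48 by construction).

The same stages are available as library calls:

```python
from pinebird import (StudyDesign, TrueParameters, simulate_dataset,
                      fit_occupancy, MCMCConfig)
from pinebird.occupancy import OccupancyModelData

ds = simulate_dataset(StudyDesign(seed=1), TrueParameters(), seed=1)
data = OccupancyModelData.from_frames(ds.sites, ds.covariates, ds.surveys)
fit = fit_occupancy(data, config=MCMCConfig(n_iter=6000, burn_in=3000, thin=3, seed=1))
print(fit.stacked("phi").mean())   # posterior mean spatial decay (per km)
```

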