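# otubayes

Joint Bayesian negative-binomial regression for longitudinal microbiome
OTU count tables.

## The problem

16S rRNA surveys record counts of operational taxonomic units (OTUs)
across samples taken over time. Raw counts are not comparable across
samples — total sequencing depth varies by orders of magnitude for purely
technical reasons — and the usual fixes (rarefaction, relative
abundances, plug-in size factors) freeze the normalization before the
analysis starts, so its uncertainty never reaches the quantities of
interest. The counts are also overdispersed, temporally dependent, and
accompanied by covariates (nutrient levels, temperature, toxin
concentrations) whose effects on each taxon are the scientific target.

`otubayes` fits one hierarchical model that does normalization, temporal
smoothing and covariate regression simultaneously, for all OTUs jointly,
so that each step borrows strength across OTUs, samples and time points
and every source of uncertainty propagates into the posterior.

## The model

Counts for OTU *j* in replicate *k* at time *t* are negative binomial,

    y_{t,k,j} ~ NB(mu_{t,k,j}, s_j),      Var = mu + mu^2 s_j,

with OTU-specific overdispersion `s_j ~ Ga(a_s, b_s)`. The mean factorizes
into a baseline and a covariate effect,

    mu_{t,k,j} = g_{t,k,j} * eta_j(X_t),
    g_{t,k,j}  = r_{t,k} * alpha_{0,j} * alpha_{t,j},
    log eta_j(X_t) = X_t' beta_j,

where `r` is a sample size factor (sequencing depth), `alpha_0` an OTU
abundance factor and `alpha_t` an OTU-time factor. Three prior devices
make this work:

- **Mean-constrained mixture priors** on `log r` and `log alpha_0`: flexible
  normal mixtures engineered so each component's mean — hence the prior and
  posterior mean of the factor — equals a fixed constant (`c_r`, `c_alpha`,
  set empirically from classical size-factor estimates). The individual
  factors stay unidentifiable, but their product `g` and the coefficients
  `beta` are identified.
- **Laplace (Bayesian-lasso) shrinkage** on `beta_{j,p}`, written as a
  normal scale mixture (`beta ~ N(0, sigma_j^2 phi_{j,p})`,
  `phi ~ Exp(lambda_j^2/2)`): true-zero effects are flattened toward zero
  while real effects survive, which matters when P is sizeable and
  covariates are correlated.
- **A process-convolution temporal prior** on `log alpha_{t,j}`: latent
  weights at M fixed basis points, smeared by a Gaussian kernel, give a
  cheap smooth Gaussian-process surrogate for each OTU's trajectory.

Inference is Metropolis-within-Gibbs MCMC with conjugate updates where
they exist, adaptive random-walk moves elsewhere, a joint shift move for
the confounded baseline factors, and uniform-prior imputation of missing
categorical covariates. See `docs/methods.md` for the full account.

## Worked example

`examples/fit_and_summarize.py` simulates a small study (20 OTUs, 15 time
points with duplicate samples, sparse true effects) and fits it with a
short chain:

```
coefficient recovery: RMSE 0.146, 95% CI coverage 0.99
shrinkage: mean |beta_hat| = 0.107 over true zeros vs 1.451 over true
  effects (ratio 13.6)
baseline recovery: mean D_j = +0.68 counts against a mean true baseline
  of 44.6
predictive check: 95% intervals cover 99.8% of the observed counts

largest effect: OTU 2, covariate x1: beta = +1.59 [+1.35, +1.84]
  -> each unit of x1 multiplies that OTU's expected count by 4.92
```

Reading the numbers: interval coverage near the nominal level and
root-mean-square error well below the true effect size (1.5) mean the
coefficients are recovered; the shrinkage ratio shows the Laplace prior
separating real effects from noise; `D_j` (the per-OTU average difference
between estimated and true baseline mean counts) near zero relative to
the baseline scale means the model-based normalization worked; and a
coefficient `beta` is read as a multiplicative effect `exp(beta)` on the
expected count — e.g. a coefficient of −0.572 on a concentration-level
indicator multiplies expected abundance by exp(−0.572) = 0.564.

The other examples: `examples/simulate_study.py` writes a synthetic
dataset (counts TSV, covariates TSV with `-1` missing codes, truth JSON)
and `examples/prior_structure.py` demonstrates the mean-constraint and
process-convolution priors numerically.

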