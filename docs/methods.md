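# Methods

## Model

For OTU `j = 1..J`, replicate `k = 1..K_i` at time `t_i` (`i = 1..n`,
`N = sum K_i` samples):

    y_{t,k,j} | mu, s_j  ~  NB(mu_{t,k,j}, s_j)

in the (mean, overdispersion) parameterization, `E[y] = mu`,
`Var[y] = mu + mu^2 s_j`, equivalently `NB(size = 1/s_j,
prob = 1/(1 + s_j mu))`; `s_j -> 0` recovers Poisson. Overdispersion is
per-OTU, `s_j ~ Ga(a_s, b_s)` (rate parameterization throughout).

The mean decomposes multiplicatively, on the log scale additively:

    log mu = r~_{t,k} + a~0_j + a~t_{t,j} + X_t' beta_j

- `r~` (log sample size factor) absorbs sequencing depth,
- `a~0` (log OTU factor) absorbs overall abundance differences,
- `a~t` (log OTU-time factor) absorbs smooth temporal drift,
- `X_t' beta_j` carries the covariate effects, the inferential target.

### Identifiability and the mean-constrained mixture prior

The decomposition is overparameterized: `(r~ + d, a~0 - d)` gives the same
likelihood for any `d`. Rather than plugging in point estimates of the
size factors, `r~` and `a~0` get flexible mixture priors whose *mean* is
pinned to a constant:

    p(x) = sum_{l=1}^L psi_l [ w_l N(x; eta_l, v^2)
                             + (1-w_l) N(x; (c - w_l eta_l)/(1-w_l), v^2) ]

Each component's second sub-mean is *derived* from `(c, w_l, eta_l)` so
that the component mean — and hence the prior mean, for any parameter
values — is exactly `c`. Shape (skewness, multimodality) stays free via
`psi ~ Dir(d)`, `w_l ~ Beta(a_w, b_w)`, `eta_l ~ N(c, omega^2)`; `v^2` and
`L` are fixed. With the means of both factor sets anchored, the products
`g = r * alpha_0 * alpha_t` and the coefficients `beta` are identified;
the individual factors remain interpretation-free, which is accepted and
documented behaviour (their posteriors shift in opposite directions while
`g` stays put).

The constraints are set empirically (`constraints="auto"`): classical
estimates `r'_{t,k} = y_{t,k,.}/y_...` and `alpha0'_j = (1/N) sum y/r'`
are computed from the table being fitted and `c_r`, `c_alpha` are the
means of their logarithms. The acceptance suite verifies that shifting
both constraints oppositely by 0.5 changes posterior-mean baselines only
within Monte Carlo error.

One property worth knowing: the second sub-mean `(c - w eta)/(1 - w)`
diverges as `w -> 1`, so with `b_w <= 2` the prior on the factors has
infinite variance (with `b_w <= 4`, infinite fourth moment). This is
harmless for inference — the posterior is proper and the data keep the
factors in range; degenerate `w` is also clipped to `[1e-6, 1-1e-6]` — but
simulation-based calibration checks must either monitor robust (log-scale)
statistics or use `b_w > 4`, which the test suite does.

### Temporal process convolution

`a~t_{t,j} = sum_m Z(t - u_m) theta_{m,j}` with a Gaussian kernel
`Z(d) = (2 pi gamma^2)^{-1/2} exp(-d^2 / 2 gamma^2)`, M basis points
evenly spaced (endpoint-inclusive) over the margin-extended window
`[-t1', T + t2']`, and the kernel range tied to the basis resolution,
`gamma^2 = ((2T + t1' + t2')/M)^2` — taken literally with T the observed
span. The margins keep edge trajectories from being pinned toward zero;
endpoint-inclusive even spacing is the conventional reading of "evenly
spaced between -t1' and T + t2'". `theta_{m,j} ~ N(0, tau_j^2)`,
`tau_j^2 ~ IG(a_tau, b_tau)`, inducing a zero-mean GP with covariance
`tau_j^2 Z Z'` (verified against sample covariance in the tests). M should
be small enough that every kernel overlaps at least one sampled time;
otherwise that basis point's weight is informed only by its prior.

### Shrinkage regression

`beta_{j,p} | sigma_j^2, phi_{j,p} ~ N(0, sigma_j^2 phi_{j,p})`,
`phi ~ Exp(lambda_j^2/2)`, `lambda_j^2 ~ Ga(a_lam, b_lam)`,
`sigma_j^2 ~ IG(a_sig, b_sig)`. Marginalizing `phi` gives the Laplace
prior with scale `sigma_j / lambda_j` (the classical Bayesian-lasso
marginal; the quadrature oracle in the tests pins this down to 1e-8).
Continuous covariates are standardized to mean 0, variance 1 over the
observed time points; heavily skewed concentration measurements are
discretized by user-supplied breaks into ordinal levels (0 = "none"
baseline) and dummy-coded against the baseline, so each non-baseline
level carries its own coefficient, read as a log fold-change. Missing
values are supported for categorical covariates only (input code −1) and
are imputed in the sampler under a uniform prior over levels.

## Posterior computation

MH-within-Gibbs; one sweep updates, in fixed order: missing-covariate
imputation (exact conditional, enumerating the C levels), `beta`
(per-coefficient random-walk MH, vectorized over OTUs since the NB
likelihood factorizes by column), `phi` (inverse-Gaussian conditional for
`1/phi`, standard Bayesian-lasso algebra), `lambda^2` (conjugate Gamma),
`sigma^2` (conjugate inverse-Gamma), element-wise MH on `r~` and `a~0`
against likelihood × mixture prior, a joint shift move
`(r~ + d, a~0 - d)` whose likelihood ratio is exactly 1 (acceptance
decided by the two mixture priors alone — it lets the confounded overall
levels trade off directly rather than by slow diffusion), the two
mixture-parameter sweeps (exact label conditional, conjugate Dirichlet
`psi`, conjugate Gaussian `eta` — the second sub-mean is linear in `eta`
given labels, so the conditional stays Gaussian — and logit random-walk MH
for `w`, which enters the second sub-mean nonlinearly and has no conjugate
form), `theta` (per-basis-point MH, vectorized over OTUs), `tau^2`
(conjugate IG(a_tau + M/2, b_tau + sum theta^2/2)) and `log s` (MH with
the full NB likelihood). Mixture conditionals were derived independently
and every conditional is verified by density-ratio checks (1e-10) and
getting-it-right (successive-conditional) simulations.

Proposal scales follow a Robbins-Monro schedule targeting acceptance 0.44
during burn-in and are frozen afterwards, so the post-burn-in kernel is
fixed and the stationary law exact. Label switching in the mixtures needs
no handling: the mixture is a prior device and only its density enters
the posterior.

Numerical choices: all mean computations are on the log scale with an
explicit error if any exponent exceeds 700; Metropolis ratios that change
only `mu` drop the Gamma-function terms of the NB pmf (they cancel); `w`
is clipped to `[1e-6, 1-1e-6]`; `|beta|` is clamped at 1e-10 inside the
inverse-Gaussian mean; empty mixture components are refreshed from their
priors. Initialization simulates from the priors with two guards: the
starting `beta` is redrawn under capped scales (`sigma^2, phi <= 2`),
because raw draws from the heavy-tailed shrinkage hyperpriors can
overflow `exp`, and whole states are rejected until the log posterior is
finite and max log-mean is moderate. Both guards touch only the starting
point, not the kernel.

## Defaults

| parameter | default | notes |
|---|---|---|
| iterations / burn-in / thin | 25,000 / 10,000 / 2 | reference run lengths; 7,500 retained draws |
| a_lam, b_lam | 0.5, 0.5 | Gamma prior on lambda^2 |
| a_sig, b_sig | 0.3, 0.3 | IG prior on sigma^2 |
| L_r, L_alpha | 30, 50 | mixture components (fixed) |
| d; a_w, b_w; omega^2 | 10; 1, 1; 1 | mixture hyperpriors |
| v_r^2, v_alpha^2 | 1, 2 | mixture sub-normal variances (fixed) |
| a_s, b_s | 1, 2 | Gamma prior on overdispersion |
| M; t1', t2' | 13; 10, 10 | basis points and window margins, in the data's time units — rescale the margins when time is measured in years |
| a_tau, b_tau | 2, 1 | IG prior on tau^2; not dictated by any reference, chosen weakly informative with prior mean 1 on the log-trajectory variance |
| c_r, c_alpha | `"auto"` | empirical means of log classical size-factor estimates |
| OTU filter | mean count >= 5 | conventional low-abundance screen |

## Synthetic data

`synthetic.simulate_dataset` generates the verification-study conditions:
coefficients zero with probability 0.85, otherwise ±N(1.5, 0.05²) with
equal sign probability; overdispersions Ga(1, 10) (mean 0.1);
per-OTU trajectories `a cos(2 pi (t - b)) + c (t - t*)²` with
`a ~ N(0.15, 0.1²)`, `b ~ N(0, 0.5²)`, `c ~ N(0.1, 0.1²)`, `t*` the
median observation time and t in years — a yearly oscillation over a slow
drift; size factors resampled with replacement from a pool of classical
estimates. A pool computed from real data can be supplied; the shipped
default is a synthetic log-normal stand-in (depth multiplier
`lognormal(0, 0.5²)`, OTU abundance `lognormal(log 20, 1.2²)`, i.e. a
few-fold depth spread and three decades of abundance around a typical
filtered-OTU count) — recovery tests need realistic heterogeneity, not
any particular dataset's values. The default layout is 55 time points
over ~1.6 years with 2–3 replicates each and 200 OTUs; the test and
acceptance studies use a scaled-down 20 × 2 × 30 version with 4,000
iterations so the whole suite runs in minutes on one CPU — sizes are
choices of problem scale, and the recovery criteria are met at that
scale. Counts are drawn exactly from `NB(mu^TR, s^TR)` with
`mu^TR = r alpha_0 exp(alpha_t + X' beta)`; the observed covariate table
carries the missing mask while the truth keeps complete levels. Two
trajectory variants support robustness experiments: i.i.d. normal noise
(no temporal dependence) and a documented step-plus-cosine discontinuous
form (the reference for that variant prints no formula, so ours is a
package-defined stand-in and excluded from calibration claims). A
simulated all-zero sample row (possible at very low depth) would be
rejected by validation, so the generator forces one read into the row's
most abundant OTU; at realistic depths this never triggers.

What the generator does *not* emulate: real covariate correlation
structure beyond an optional AR(1)-style knob, compositional coupling
between OTUs (counts are conditionally independent given mu), taxonomic
structure, and zero-inflation beyond what NB overdispersion produces.
Passing recovery tests therefore demonstrate correctness of the
inference under the model's own assumptions, not robustness to every
feature of real surveys (the discontinuous-trajectory variant probes one
such violation).

## Summaries and diagnostics

Credible intervals are equal-tailed quantile intervals (level 0 degrades
to the median); highest-density intervals are not used. The
baseline-recovery metric is `D_j = (1/N) sum_{t,k} (g_hat - g^TR)`, with
the posterior mean taken first — that convention is fixed and asserted.
Posterior-predictive checks resimulate full count tables per retained
draw. Effective sample sizes use Geyer's initial-monotone-sequence
estimator (cross-checked against arviz in the tests); Monte Carlo
standard errors are `sd/sqrt(ESS)`.

## Known limitations

- Coefficients are constant in time; no spike-and-slab selection.
- `r`, `alpha_0`, `alpha_t` individually are not interpretable — only
  `g` and `beta` are reported quantities.
- The temporal prior assumes smoothness; discontinuous dynamics degrade
  baseline estimates (the step variant exists to demonstrate this).
- Continuous covariates cannot be missing.
- Memory: draws store full parameter blocks; derived `g`/`mu` matrices
  are streamed rather than materialized, but very large J with long
  chains will want a larger thinning interval.
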