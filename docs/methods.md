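# Methods

## The task and its simulator

The package models a loss-frame probabilistic learning task: on each of 200
trials a participant chooses between two cards, each displaying a loss
magnitude drawn independently and uniformly on [$1, $5] (continuous draws;
dollar rounding is presentation only, payoffs use the raw values). One card
is "correct" (loses $0); choosing the other loses that card's magnitude.
The correct card is drawn Bernoulli per trial from fixed contingencies: in
the 100-trial **stable** context one card loses with probability 0.75 and
the other 0.25 throughout; in the 100-trial **volatile** context the
assignment is 0.80/0.20 and reverses at trial offsets 25, 50 and 75 within
the block. Context order (stable first vs volatile first) is randomized per
subject, as is which card starts as the high-loss card; correct-card draws
are independent across trials (no run-length constraints). Feedback is
complete: the correct card is revealed whatever was chosen, so learners
observe the binary sequence `u[t] = 1{card 1 lost}` regardless of choice.

Continuous-uniform magnitudes are the only simple randomization scheme
consistent with the reported per-participant ranges of close and far
magnitude pairs: under independent U[1,5] draws the absolute difference is
triangular on [0,4], giving P(|d| <= 1) = 7/16 (mean 87.5 of 200 trials)
and P(|d| >= 3) = 1/16 (mean 12.5); integer-valued schemes put these means
far outside the reported ranges ([69, 101] and [6, 25]).

## Learning models

All four candidate perceptual models track the predicted probability that
card 1 loses; card 2 quantities are complements. Initial states are fixed,
not fitted: a neutral prior belief (prediction 0.5; `mu2 = 0`, `sigma2 = 1`
for the filters, `mu3 = 1`, `sigma3 = 1` at the third level).

* **Rescorla–Wagner (`rw`)** — delta rule `v' = v + alpha (u - v)`,
  learning rate `alpha` in [0, 1] (fitted on the logit scale).
* **Sutton K1 (`k1`)** — delta rule whose log learning rate `b` adapts with
  the correlation of the current prediction error and a decaying trace `h`
  of past errors: `b' = b + mu_k1 * delta * h`; the rate `exp(b')` is capped
  at 1 so the probability estimate stays in [0, 1];
  `h' = h max(0, 1 - rate) + rate * delta`. Fitted parameters: meta-learning
  rate `mu_k1` (log scale) and initial log rate `b0`.
* **Two-level HGF (`hgf2`)** — binary hierarchical Gaussian filter. With
  prediction `s = logistic(mu2)`, prior variance `sigma2_hat = sigma2 +
  exp(omega)`, posterior precision `pi2 = 1/sigma2_hat + s(1-s)`:
  `mu2' = mu2 + (u - s)/pi2`, `sigma2' = 1/pi2`. The log-volatility `omega`
  (identity scale) sets the speed of belief updating. The trajectory also
  records the outcome prediction error `delta1 = u - s` and the
  precision-weighted prediction error `eps2 = delta1 / pi2` (a derived
  series, not a parameter).
* **Three-level HGF (`hgf3`)** — as `hgf2` with effective log-volatility
  `kappa*mu3 + omega`, plus a Gaussian level-3 update of `(mu3, sigma3)`
  driven by the level-2 volatility prediction error with step variance
  `theta` (fitted on the log scale). The coupling `kappa` is fixed at 1 by
  default, the common convention for binary designs where `kappa` and the
  level-3 scale are not separately identifiable. Parameter regimes that
  drive the level-3 precision non-positive are flagged invalid and rejected
  as fit candidates.

## Observation model

Beliefs and magnitudes map to expected values `v_i = -p_i * m_i^rho`
(`p_1 = s`, `p_2 = 1 - s`), and `P(choose card 1) =
logistic(beta (v1 - v2))` with inverse temperature `beta >= 0` and loss
sensitivity `rho > 0` (both fitted on the log scale). `rho` enters as a
power on magnitude rather than a multiplicative weight: in a loss-only
two-option softmax a multiplicative weight is exactly collinear with
`beta` (only their product would be identifiable), while the power form
leaves both identifiable and preserves the reading that larger `rho` means
greater sensitivity to magnitude differences. One parameter set covers all
200 trials in presentation order; the first trial uses the initial
prediction 0.5. Choice probabilities are clamped to `[1e-12, 1 - 1e-12]`
so log-likelihoods are always finite; trajectory divergence returns a
finite sentinel that the optimizer treats as arbitrarily bad.

Candidates `rw`, `k1`, `hgf2`, `hgf3` fix `rho = 1`; the `*_loss` variants
(`hgf2_loss`, `hgf3_loss`) fit it.

## Fitting, evidence, model selection

Per subject and model, MAP estimation maximizes log-likelihood + log-prior
on the unconstrained scale (L-BFGS-B; default 10 restarts jittered by one
prior SD around the prior mean, the first start at the mean; objective
tolerance 1e-10). Priors are weakly informative Gaussians:
`omega ~ N(-3, 16)`, `log beta ~ N(0, 4)` (the extra width accommodates the
loss-frame expected-value scale), `log rho ~ N(0, 1)`,
`logit alpha ~ N(0, 4)`, `log theta ~ N(-6, 16)`, `log mu_k1 ~ N(-3, 16)`,
`b0 ~ N(-2, 4)`; all are overridable through config so alternative prior
tables can be dropped in.

Log model evidence is the Laplace approximation
`logpost(MAP) + (d/2) log 2*pi - (1/2) log det H`, with `H` the numerical
(central-difference) Hessian of the negative log posterior; non-positive-
definite Hessians are eigenvalue-floored and flagged, with a BIC-style
fallback if the determinant is still unusable. Random-effects Bayesian
model selection uses the variational Dirichlet scheme: per-subject model
posteriors `u_nk proportional to exp(lme_nk + digamma(alpha_k) -
digamma(sum alpha))` iterated against `alpha = alpha0 + sum_n u_n` to a
1e-4 concentration tolerance (uniform prior `alpha0 = 1`); exceedance
probabilities come from 1e5 seeded Dirichlet draws.

Extreme inverse-temperature estimates are winsorized before regression:
values beyond `Q3 + 3*IQR` (linear-interpolation quartiles) are replaced by
the maximum non-extreme value plus one sample SD of the non-extreme values,
with a report of originals and replacements.

## Stay/shift regressions

The stay table codes, per analyzable trial, whether the current choice
repeats the previous one, the previous trial's outcome (incurred = 1,
avoided = reference), context (volatile = 1), the current trial's
chosen-minus-unchosen magnitude difference (mean-centered over analyzed
rows), mean-centered age, context-order randomization, and the substance-
use covariate. Trial 1 and the first trial of the second context block are
excluded — the within-block lag is the only coding that never crosses a
contingency regime the participant has not yet experienced — so a complete
session contributes 198 rows. The severity covariate (ASI-X) is summed
years of regular use across substances, square-root transformed then
z-scored (sample SD), in that order.

Two mixed-effects logistic models are fitted: task effects
(`stay ~ prev_outcome * context + lmd_c + age_c + randomization + (1 | subject)`)
and severity moderation (the same with `* asix_z`). Estimation maximizes
the marginal likelihood integrating the random intercept by adaptive
Gauss–Hermite quadrature (9 nodes by default; node count configurable, 1 =
Laplace), with Wald z tests from the numerical Hessian of the marginal
log-likelihood and simple slopes as delta-method linear contrasts
(+-1 SD for the continuous moderator, the coded levels for binary ones).
Parameter regressions are OLS of each fitted parameter (winsorized
`log beta`) on `asix_z`, randomization and centered age.

Models with a random slope (used by the power harness) are estimated by the
Laplace approximation with the fixed effects profiled at the joint
penalized mode — the lme4 strategy: the outer optimizer (Nelder-Mead) sees
only the two variance parameters, the inner step is a joint Newton solve
through the Schur complement over the block-diagonal random-effects
Hessian, and the Wald covariance of the fixed effects is the inverse Schur
complement, conditional on the variance estimates. The intercept-only path
reproduces `glmer(..., nAGQ = 9)` coefficients and standard errors to
about 1e-5 on test instances; profiled-slope fits match `glmer`'s variance
components closely while the fixed effects sit at the joint mode
(`nAGQ = 0` flavor), which differs from the Laplace-maximizing values by a
fraction of a standard error at the cohort sizes used here.

## Power simulation

The harness simulates replicate cohorts directly from the moderation
model's data-generating process: 137 subjects x 198 analyzable trials;
fixed effects at magnitudes like the study-scale stay/shift estimates
(intercept 0.4; previous outcome -0.669; context -0.101; ASI-X -0.1;
previous outcome x context 0.124; context x ASI-X 0.083; three-way 0;
magnitude-difference -0.05; age and randomization 0); previous outcome
incurred with probability 0.4 per trial; ASI-X drawn from the cohort
generator (25% zeros + gamma) and transformed; a random intercept
(SD 0.8) **and a random previous-outcome slope (SD 0.5)** per subject.
Each replicate refits the same model and applies the Wald test to the
previous-outcome x ASI-X coefficient; power is the rejection fraction with
a Wilson binomial CI, and failed fits are excluded and counted.

The random slope is a deliberate design choice, for two reasons. First,
between-subject variation in outcome sensitivity is the phenomenon the
moderation test is about; a generative process in which every subject
shares one previous-outcome effect (given ASI-X) is not a realistic null
field for that test. Second, it is required for the test to be
non-trivial at this design size: with a random intercept only, the
per-subject previous-outcome slope is estimated with sampling SD about
`sqrt(1/(198 * 0.24 * 0.21)) ~ 0.32`, so the interaction SE is about
`0.32/sqrt(137) ~ 0.027` and an effect of 0.17 log-odds is detected
essentially always. Slope heterogeneity of SD 0.5 — the same order as the
moderation effects the model is built to detect — raises the SE to about
`sqrt((0.32^2 + 0.5^2)/137) ~ 0.05`, putting power for 0.17 near 90%. The
fitted model carries the same random slope as the generative one; fitting
an intercept-only model to slope-heterogeneous data would inflate the
type-I error of the interaction test to ~0.24 and make the "power"
estimate meaningless. All nuisance values are config fields logged with
every run.

## Synthetic cohorts: what they emulate, and what not

The cohort generator stands in for the study sample: per-subject
generative parameters are linear in the transformed severity covariate on
the unconstrained scale, plus Gaussian noise (which keeps native-scale
constraints automatic). Defaults: `omega ~ -3 + 0.18 z + N(0, 1)`,
`log beta ~ 0.5 - 0.307 z + N(0, 0.25)`, `log rho ~ 0.5 + 0.14 z +
N(0, 0.25)`; link magnitudes follow the study-scale regression estimates,
the `log rho` center reflects conventional loss-aversion magnitudes near 2,
and the residual SDs are moderate so that individual fits are informative.
Severity: 25% exact zeros plus gamma(shape 1.5, scale 8) years (mean ~12);
age normal(40, 12) truncated to [18, 65]; context order randomized 1:1.

Passing recovery and sign gates on these cohorts shows that the estimation
and regression machinery is consistent under its own assumptions at the
study's scale. It does not show that real participants follow an HGF, that
real severity links are linear on these scales, or that attention lapses,
perseveration kernels, response-time pressure or within-session drift —
all absent from the generator — would leave the conclusions intact.

## Numerical conventions

Exponentials of fitted quantities are argument-clamped (|arg| <= 700) so
extreme optimizer candidates stay finite; the logistic inverse transform is
clamped to [1e-12, 1 - 1e-12]. Quartiles use linear interpolation
(type 7). Restart sequences are seed-deterministic, so enlarging the
restart count can only improve the best objective. BMS ties break toward
the lower model index via argmax only after exceedance estimation; tied
evidences give symmetric exceedance by construction. Stage seeds in the
pipeline derive from the global seed by fixed offsets and are written to a
provenance sidecar with a config hash.

Default problem sizes in the test-suite Monte Carlo checks: 137 subjects
for cohort-level gates, 50 subjects x 6 models for model recovery, 200
replicates for the power band, 25-60 replicates with 40-60 subjects and
60 trials for the scaled-down calibration and monotonicity properties.

## Known limitations

* The exact supplementary equations of the original toolbox models
  (including the precise utility form for the loss-sensitive softmax and
  the prior table) are not reproduced here; the canonical binary-HGF,
  Sutton K1 and delta-rule formulations with documented default priors are
  used instead, and all priors are overridable.
* Laplace evidence is a local approximation; strongly multimodal subjects
  are handled only through restarts.
* Random-effect covariance is diagonal (no intercept-slope correlation),
  and slope-model fixed effects are profiled at the joint mode rather than
  Laplace-maximized (see above).
* Protected exceedance probabilities, hierarchical prior re-estimation and
  MCMC posteriors are out of scope.
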