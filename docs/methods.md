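# Methods

## The compositional representation

A subject's day is x = (x_MVPA, x_LPA, x_SB, x_sleep), strictly positive
minutes closing to 1440.  Because only ratios are informative, modelling is
done in isometric log-ratio (ilr) coordinates.  The default basis is the
pivot basis with part order (MVPA, LPA, SB, sleep):

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gmean(x_{j+1..D}) ),  j = 1..D-1,

so z1 contrasts MVPA against everything else, z2 LPA against SB+sleep, z3 SB
against sleep.  Any other orthonormal basis is an orthogonal rotation of
these coordinates; with a full shared covariance the mixture likelihood,
posteriors, BIC and entropy are therefore basis-invariant (tested), and the
basis choice only affects how coordinates are reported.  Zero parts are
rejected with an explicit error rather than imputed: daily aggregation is
responsible for strictly positive parts, and a zero reaching the transform
indicates upstream data problems.  Minutes/day (total 1440) is the canonical
unit; proportions (total 1) are supported.

## Accelerometry

Inputs are 5-s epochs of ENMO (milli-g) with wear and sleep flags; raw
100-Hz processing (calibration, ENMO computation, non-wear and sleep
detection) is upstream of this package.  Cutpoints are half-open intervals
SB [0, 36), LPA [36, 201), MVPA [201, inf) mg, which preserves the published
boundary behaviour (35.9 -> SB, 36 -> LPA, 201 -> MVPA) while classifying
the continuum point 200.5 that the printed "36-200 / >= 201" bands leave
unstated.  The sleep flag dominates ENMO.  Days run midnight to midnight; a
day with >= 16 h wear is proportionally re-closed to 1440 min, shorter days
are dropped.  A subject is valid with >= 3 valid school days, >= 1 valid
weekend day, and wear present in each 15-min bin of the 24-h cycle pooled
across the week (the per-day variant is configurable; the pooled reading is
the default because a per-day rule would be redundant with the 16-h rule).
The subject composition is the arithmetic mean of valid-day minutes,
re-closed — the standard accelerometry convention for averaging days.

## Outlier screening

Robust distances come from the minimum covariance determinant estimator
(support fraction 0.75) on the ilr coordinates; the flag threshold is
sqrt(chi2_{D-1}(0.975)) = 3.0575 for three coordinates.  Flagged subjects
are excluded before mixture fitting but retained in outputs for sensitivity
reruns; Cohen's kappa after Hungarian relabelling quantifies assignment
agreement between fits with and without them.

## Latent profile model

The typology model on z in R^3 is a K-component Gaussian mixture with class
means mu_k, mixing weights pi_k and a single pooled covariance Sigma
(within-class variances and covariances equal across typologies):
q = (K-1) + 3K + 6 free parameters.  Estimation is EM, best of `n_starts`
initialisations (alternating k-means++ one-hot responsibilities and random
Dirichlet responsibilities), convergence when the relative log-likelihood
change drops below `tol`.  Defaults: 50 starts for headline fits (20 in the
pipeline, fewer in replicated simulations), tol 1e-8, max 1000 iterations,
ridge 1e-10*trace(Sigma)/d on covariance collapse, condition-number guard at
1e12.  The per-iteration log-likelihood trace is stored and its monotonicity
asserted in tests; `sklearn` GaussianMixture with tied covariance serves as
an independent oracle for the maximised likelihood.

Diagnostics: BIC = -2l + q ln n, AIC = -2l + 2q, relative entropy
1 - (-sum p ln p)/(n ln K) (1 = crisp, 0 = uninformative, undefined at
K = 1), and the smallest expected class share.  Model selection excludes
solutions whose smallest class is below 10% of the sample, then takes the
lowest BIC.  A VLMR gate (require p < 0.05 to prefer K over K-1) is
available but off by default: published practice treats the test as one
input among interpretability and size considerations rather than a hard
rule, so the gate is a sensitivity switch.

The class-comparison test has two modes.  `lmr_adjusted` applies a
Bartlett-type correction to the likelihood ratio, LR' = 2*dl / (1 +
1/(dq ln n)), referred to chi-square with dq degrees of freedom — a fast
analytic approximation.  `bootstrap` draws B parametric-bootstrap datasets
from the (K-1)-class fit, refits both models on each with the same
estimation effort as the observed fit, and returns
(1 + #{boot >= observed})/(B + 1).  The bootstrap mode is the calibrated
reference (its size is verified by simulation); the analytic mode is for
quick screening inside the pipeline.  Tiny negative likelihood differences
(within EM convergence tolerance) are clamped to zero; substantial ones
raise, demanding a refit.

Typologies are labelled by compositional-mean MVPA, descending: Workers
(highest), Queens (lowest), Drones (middle of a 3-class solution); ties
break by LPA.  Modal assignment breaks posterior ties toward the lowest
class index so results are deterministic.  Weighted descriptives use the
posterior probabilities as weights; the weighted SD uses the
reliability-weight correction sum(w)/(sum(w)^2 - sum(w^2)) * sum w (x -
xbar)^2, appropriate because posteriors are precision-type, not
frequency-type, weights (with crisp posteriors it reduces to the ordinary
ddof-1 subgroup SD).

## BCH distal-outcome regression

Let D[k,s] = P(assigned s | true k), estimated from the posteriors
(proportional mode, the default: D = P'A / colmass with A = P; modal mode
uses one-hot modal assignments).  Each subject's BCH weight row is
w_i = p_i D^{-1}; rows sum to one and entries may be negative.  The distal
regression expands the data to n*K pseudo-records (class indicator s,
weight w_is) and solves weighted least squares of the (log-)outcome on
class dummies (reference: Workers), covariates (sex, centred age, birth
weight, unhealthy snacking, parental obesity, parental university
education) and interaction terms (age x typology in all children models and
the adolescent BMI-z model; age x sex additionally for children FM% and
FMI).  Because weights can be negative, the normal equations and the
subject-clustered sandwich covariance are computed directly with linear
algebra rather than through a WLS routine that requires positive weights.
CIs are B +/- 1.96 se; log-scale coefficients are reported alongside
exp(B).  With crisp posteriors D = I and the estimator reduces exactly to
classify-then-regress (tested to 1e-9); under realistic uncertainty its
bias for a known class effect is verified by simulation to be under 0.03
and smaller than the naive modal regression's.

The covariate comparison across typologies is the ML three-step analogue: a
multinomial logit of true class on the covariate, observed through the
modal assignment with misclassification rates fixed at D; a Wald test on
the covariate slopes (numerical Hessian of the analytic gradient, L2
penalty 1e-6 against separation) gives the overall p-value.  Its size and
power are simulation-verified.

The school screening uses the one-way ANOVA variance-component estimator
(negative components truncated at zero) for the ICC and a likelihood-ratio
test of the school random intercept (statsmodels MixedLM, ML) with the
50:50 chi-square boundary mixture for the p-value.  It is a screening
statistic, not a full mixed-model analysis.

Rubin's rules pool per-imputation estimates: T = Wbar + (1 + 1/m)B with
Barnard-Rubin degrees of freedom; with a single imputation or zero
between-imputation variance the reference is normal.

## Missing data

Little's MCAR test uses EM estimates of the mean and covariance of the
numeric variables under normality; the statistic sums pattern-wise
Mahalanobis discrepancies of observed-variable means, df = sum_j |o_j| - p.
It is reported, never gating: the pipeline verifies rather than assumes
MCAR.  Imputation is chained equations with m = 5 datasets and 11 sweeps
(the study protocol): continuous variables by predictive mean matching
(Bayesian draw of the regression parameters, type-1 matching, 5 donors), so
imputed values always lie in the observed support; binary variables by a
Bayesian logistic draw (ridge-stabilised IRLS).  All covariates, outcomes
and composition information available in the supplied table serve as
predictors.  Parental BMI is imputed on the continuous scale and parental
obesity re-derived as BMI >= 30 of at least one parent afterwards (same for
the university-education flag), matching how the flags are defined.
Observed cells are never altered and a fixed seed makes the procedure
bit-reproducible.

## Synthetic cohorts

The generator draws true class from the mixing weights, ilr coordinates
from a Gaussian around the class component's ilr image (shared covariance),
covariates from the group's marginal distributions, and outcomes from
log-linear (BMI z: linear) models.  Preset parameters and their sources:

| parameter | children | adolescents | basis |
|---|---|---|---|
| n | 374 | 317 | study group sizes |
| mixing | 0.80/0.20 | 0.41/0.48/0.11 | reported typology shares |
| component compositions | (63.7, 310.5, 547.6, 518.2), (31.4, 259.9, 621.2, 527.5) | (56.2, 255.9, 658.6, 469.3), (31.7, 248.6, 687.4, 472.3), (16.6, 231.5, 734.9, 457.0) | reported compositional means |
| ilr covariance | 0.04 I | 0.04 I | config default (see below) |
| class effects, log FM%/FMI/VAT | Queens: 0.32/0.36/0.51 | Drones: 0.13/0.14/0.14; Queens: 0.14/0.16/0.31 | reported coefficients |
| class effects, BMI z | Queens: -0.01 | Drones 0.04; Queens 0.16 | reported coefficients |
| girls / snacking / age range | 57%, 41.7%, 8-13 y | 57.7%, 25.6%, 14-18 y | reported margins |
| birth weight | N(3.4, 0.5) kg | N(3.3, 0.6) kg | reported mean/SD |
| parental BMI | mother N(25, 4), father N(26.8, 3.3) | same | calibrated so P(either >= 30) is about 0.25 |
| parental university (each) | 0.314 | 0.314 | so P(at least one) is about 0.53 |
| log-scale residual SDs | 0.41/0.52/0.60 (FM%/FMI/VAT), BMI-z 1.15 | 0.42/0.53/0.57, BMI-z 1.00 | from reported coefficients of variation |
| missingness rates | 27, 46, 79, 24, 61 out of 691 | same | reported missing counts |
| schools | 11, intercept SD 0 | same | no school variance was found, so the default emulates that finding |

Covariate effects on outcomes are small plausible values applied to centred
covariates (e.g. +0.18 on log FM% for girls, +0.45 on BMI z for parental
obesity), chosen once so that reference-class outcome means match the
reported descriptives; intercepts carry the lognormal -sigma^2/2 correction
so arithmetic means are targeted.  One empirical caveat: with the reported
component means, the 0.04 I within-class covariance yields a fitted 2-class
relative entropy near 0.8 — crisper classification than the 0.54 the real
cohort showed.  Simulations that need the low-certainty regime (the
BCH-vs-naive bias comparison) therefore inflate the covariance to 0.12 I,
which lands entropy in the 0.5-0.6 band.  The generator emulates
between-subject structure only: day-to-day variation is a simple
logistic-normal scatter, and the epoch emitter produces schematic days
(contiguous night sleep, shuffled one-minute waking runs) sufficient for
aggregation round-trips, not realistic diurnal profiles.  Passing tests
demonstrate correctness of the estimators under the assumed data-generating
model, not robustness to real-world violations of it (non-normal ilr
scatter, informative missingness, wear-time artefacts).

## Problem sizes in the test suite

Replicated simulations run at the study's n (374) with reduced EM start
counts (4-6) and moderate replication counts (20-200 depending on the
check; the bootstrap LRT size uses 150 outer replications with B = 39 at
n = 100 in one dimension).  These sizes keep the full suite to a few
minutes while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- The LMR-adjusted p-value is an operationalisation of the published
  correction (the original derivation leaves implementation details open);
  the parametric bootstrap is the calibrated reference.
- The ML three-step covariate test fixes the error matrix at its estimate
  and ignores its sampling variability, as is standard; p-values are
  slightly conservative in the simulations reported by the test suite.
- The school screening is deliberately minimal (one random intercept, ML);
  it is not a substitute for a full multilevel analysis.
- Compositions with structural zeros are out of scope; the package fails
  loudly rather than imputing them.
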