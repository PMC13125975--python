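# Methods

## Models

All three variants are cumulative logit models for clustered ordinal responses
y_ij in {1..k} with strictly increasing thresholds theta_1 < ... < theta_{k-1} and
cluster random intercepts. The plain random-effects proportional odds model
(`cumulative_re`) carries a single intercept b_il ~ N(0, sigma^2). The two
dispersion variants carry a bivariate intercept (b_il, b_id)' ~ N(0, Sigma_b) with
Sigma_b = [[sigma_l^2, sigma_ld], [sigma_ld, sigma_d^2]]:

* **location-scale**: eta_ijr = (theta_r - x_ij'beta - b_il) / exp(z_ij'alpha + b_id).
  The whole location expression is divided by the log-linear scale term; positive
  alpha components mean more latent variability (mass moves to extreme categories).
* **location-shift**: eta_ijr = theta_r - x_ij'beta - b_il + (r - k/2)(z_ij'alpha + b_id).
  The shift term moves thresholds symmetrically around the middle; positive shifts
  widen the inner intervals (mass moves to the middle categories). The shifted
  thresholds must stay increasing; parameter/random-effect values violating the
  ordering are treated as log-likelihood -inf during estimation (the optimizer
  backs away), and the data generator redraws covariates for violating rows.

No intercept enters the dispersion design: a constant shift is absorbed by the
thresholds (location-shift) or by a global rescaling (location-scale), so it is not
identifiable; cluster-level dispersion is carried by b_id.

## Marginal likelihood

The cluster likelihood integrates the product of category probabilities over the
random-intercept distribution. We use adaptive Gauss-Hermite quadrature: nodes are
centered at the joint posterior mode of (b_il, b_id) and scaled by the Cholesky
factor of the posterior curvature. With `n_points = 1` (the default) this is the
Laplace approximation; accuracy is data dependent and `n_points` is configurable
upward (on 3-observation test clusters, 5 points agree with dense 400x400 grid
integration to ~1e-7 relative error; 1 point to ~1e-3).

Modes are found by damped Newton iterations with analytic gradient and Hessian of
the log integrand (tolerance 1e-8 on the gradient max-norm by default, 50
iterations maximum), re-centered at every likelihood evaluation and warm-started
from the previous one. The Hessian is shifted to be safely negative definite where
the integrand is locally non-concave (possible for location-scale). Category
probabilities F(a) - F(c) and the derivative ratios f(a)/p, f(c)/p are evaluated on
the log scale (numpy reference path) or in direct space with a log-scale fallback
when p < 1e-12 (compiled kernels); the two paths agree to ~1e-14 and the kernels
are only an accelerator.

If Sigma_b is numerically zero the fixed-effects log-likelihood at b = 0 is
returned; if only the dispersion block is zero (sigma_d^2 = sigma_ld = 0) the
integral degenerates to one dimension over b_il and is computed exactly that way,
which makes the reduction of both dispersion variants to `cumulative_re` exact.

## Penalty and optimization

The penalized objective subtracts an adaptive LASSO + fusion penalty from the
marginal log-likelihood. Continuous and binary covariates get plain L1 terms with
weights 1/|unpenalized estimate| (capped at 1e6); each ordinal covariate gets
fusion terms over all pairwise level differences including the reference level
(weight 1/|difference of unpenalized estimates|, capped), so fusing a level with
the reference excludes it. Ordinal dummies carry only the fusion terms. Thresholds
and Sigma_b are never penalized.

**Lambda calibration.** Tuning parameters are expressed per observation: the
objective subtracts N * J where N is the number of observations. This matches the
convention in which the penalty is written into each observation's likelihood
contribution, and it is the scale on which grids like lambda in {e^-10, ..., e^-2}
span the range from negligible to full shrinkage at N ~ 1000; with the penalty
added once in total, those lambdas would be inert.

Each |u| is smoothed to sqrt(u^2 + epsilon) with epsilon = 1e-6 so that a
quasi-Newton method applies. Optimization runs L-BFGS-B over an unconstrained
parameterization — thresholds as (theta_1, log-increments), Sigma_b as a Cholesky
factor with log-diagonal — with batched finite-difference gradients (central by
default, one-sided in the high-volume simulation pipelines), evaluated through the
same mode-finding machinery so the objective is smooth in the parameters.

Smoothing never yields exact zeros, so selection is read off by thresholding:
coefficients below `zero_tolerance` = 1e-3 (standardized scale) are excluded and
level pairs within `fuse_tolerance` = 1e-3 are merged transitively (union-find;
the reference level participates). The selected structure is refit without penalty
— excluded coefficients fixed at zero, fused groups sharing one free coefficient —
yielding standard errors by the delta method from the observed-information inverse,
and t-based confidence limits with (number of clusters - 1) degrees of freedom, a
convention chosen for cluster-level inference.

## Tuning

`tune_grid` fits the penalized model over a grid of (log lambda_l, log lambda_d)
pairs, warm-starting along the grid (ascending lambda_d within each lambda_l row,
rows started from the row head), with adaptive weights computed once from the
unpenalized training fit. Once the whole dispersion component is shrunk to zero
within a row, the remaining larger lambda_d points are copies of the current fit
(they cannot differ), which prunes the saturated corner.

Each fit is scored by the predictive log-likelihood of a validation sample —
the same marginal (integrated) likelihood evaluated on new data; clusters present
in training are still integrated, not conditioned on their EB estimates. The
returned pair is, by default, the sparsest pair whose predictive log-likelihood is
within one standard error of the best grid point ("within_se"), where the SE of
the deficit is estimated from the per-cluster log-likelihood differences. The
rationale: removing a truly inert dispersion block changes the validation
log-likelihood by far less than its sampling error, so the plain argmax is decided
by noise and systematically under-selects; the one-SE rule is the standard device
for this situation in penalized regression. The plain argmax (with exact ties
broken toward sparsity) is available as `selection_rule="max"`.

## Evaluation

Predictive deviance is -2x the predictive log-likelihood. The ranked probability
score averages, over observations, the squared differences between predicted
cumulative probabilities (integrated over the random-effect prior by 15-point
Gauss-Hermite quadrature) and the observed step function; it lies in [0, k-1] and
the final summand (r = k) is always zero but included as written. AIC/BIC use
deviance + {2, log N} x the number of free parameters.

## Synthetic data and the selection experiment

The generator draws, per cluster, (b_il, b_id) ~ N(0, Sigma_b), then per
observation two covariates uniform on [-1, 1] and one 4-level ordinal covariate
uniform over its levels (uniform is the minimal assumption and keeps all dummy
cells populated), sets z = x, and samples y from the model's category
probabilities at the configured truth. Defaults are the benchmark design: k = 3,
thresholds (-1, 1), beta = (-0.2, 0.2, -0.5, 0.5, 0.5), alpha = (-0.4, 0.4, 0, 0, 0),
Sigma_b = [[0.10, 0.02], [0.02, 0.10]]; setting 1 has 50 clusters of 25, setting 2
has 30 clusters of 40. Under this truth the ordinal covariate's levels 3 and 4
share one location effect and the covariate has no dispersion effect.

`run_selection_experiment` repeats, per replication: draw a training sample and an
equal-sized validation sample sharing the same cluster intercepts (fresh covariates
and responses — mirroring analysis designs where every cluster appears in every
split), standardize covariates on the training sample (sample SD, record reused
for validation), fit unpenalized, build adaptive weights, search the integer grid
log lambda in {-10, ..., -2} squared by predictive log-likelihood with the
within-one-SE rule, and record the selected model. Rates: TPR of a truly nonzero
covariate is the fraction of replications where any of its columns survives; TNR
of the truly-zero ordinal dispersion block requires all its dummies excluded;
fusion recovery requires levels 3 and 4 to form exactly one fused group.
Replication seeds spawn deterministically from the master seed.

What the generator does **not** emulate: real questionnaire data have covariate
dependence, unequal cluster sizes, non-logistic latent noise and missingness; the
experiments therefore validate the selection machinery under the stated design,
not robustness to those features.

## Problem sizes used by the test suite and acceptance script

Statistical checks are scaled to run on one CPU: the test suite runs the four
selection-experiment cells with the full 9x9 integer grid at 28 replications for
the location-shift cells and 14 for the (roughly 3x costlier) location-scale
cells, and the parameter-recovery study (200 clusters, i.e. quadrupled setting 1)
at 12 replications with a 5x5 grid; `scripts/acceptance.py` defaults to 12
replications per cell and 8 recovery replications. High-volume pipelines use
one-sided finite differences, a 60-iteration cap per penalized fit and a mode
tolerance of 1e-7; pilot runs showed selection rates indistinguishable from the
tight-tolerance settings. Binomial uncertainty at these replication counts is
roughly +-0.09-0.11 per rate.

## Known limitations

* One-point (Laplace) quadrature can bias variance-component estimates for small
  clusters; `n_points` is configurable but the benchmark experiments use 1.
* The optimizer treats the smoothed penalty by quasi-Newton steps; with capped
  adaptive weights and large lambda the objective is very ill-conditioned and the
  extreme grid corners may stop on the iteration cap (they are effectively fully
  shrunk at that point).
* Selection thresholds (1e-3) interact with the smoothing constant: a coefficient
  pinned by the smoothed penalty settles at a magnitude of order
  curvature*estimate/(lambda*weight/sqrt(epsilon)), which the defaults place well
  below 1e-3 for decisively penalized effects but near it in transition regions.
* `split_train_valid_test` supports cluster-stratified splits and cluster
  holdouts; sensitivity-style resampling experiments are compositions of these
  utilities, not built-in procedures.
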