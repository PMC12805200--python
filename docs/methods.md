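# Methods

## The model

A forced-choice block presents `B` statements that a respondent orders
from most to least self-descriptive, with ties forbidden. Statement `k`
measures trait `theta_{t(k)}` through a linear utility with slope `a_k`
and intercept `c_k`. The pattern model assigns ranking pattern `j` the
mean utility

    V_j(theta) = sum_k s(r_jk) (a_k theta_{t(k)} + c_k),    s(r) = B - r,

where `r_jk` is statement `k`'s rank in pattern `j`: the least favourable
statement scores 0 and every one-rank advancement adds one increment of
the statement's utility, the adjacent-category scheme familiar from the
generalized partial credit model. With extreme-value pattern errors the
response probabilities are the softmax `P_j = exp(V_j) / sum exp(V_j')`,
so the log odds of two patterns is the difference of their mean utilities
— a conditional logit in which each rank-level change contributes one
utility increment. One intercept per block (statement 1's) is fixed at 0
for identification; when all statements of a block share a trait one
slope would also need fixing, which multidimensional designs avoid.

An *alternative* scheme replaces the constant per-rank increment with
rank-specific intercepts `c_{k,r}` (the slope part unchanged). It adds
`B(B-2)` parameters per block and is exposed in the block types and
probability functions; estimation covers the primary scheme, which is the
parsimonious model of interest.

Patterns are enumerated lexicographically by the rank-1..rank-B statement
sequence, so code 1 of a triplet is the ordering (1,2,3). Beyond the
first entry the coding is a package convention; any fixed bijection works
because the model is defined on patterns, not codes.

### Reduced formats

PICK (choose the most descriptive) and MOLE (most and least) observe a
coarsening of the pattern space: their probabilities are sums of pattern
probabilities over every full ranking the partial response does not
contradict — `(B-1)!` rankings for a PICK choice, `(B-2)!` for a MOLE
pair. Graded pairs treat each of `C` categories as a "pattern" with
scores `(C-g, g-1)` for category `g` (user-overridable — the default is a
symmetric linear partial-credit split chosen because it reduces to the
RANK pair at `C = 2`). HFCL blocks (Likert ratings with ties forbidden)
treat every no-tie rating vector as a pattern with statement scores
`rating - 1`. All five formats run through one likelihood engine keyed on
a score matrix and a response-grouping, so simulation, estimation, and
scoring handle them uniformly.

### Sequential-selection baseline

The comparison model ranks by repeated choice — a normalized logistic
selection among remaining statements at each stage — with one intercept
per triplet fixed. For pairs it coincides exactly with the pattern model;
for triplets the two models have identical free-parameter counts, which
makes their AIC difference equal their BIC difference on common data.
Block sizes above three are out of scope for the baseline.

## Estimation

Traits follow a standard multivariate normal with correlation matrix `R`
(means 0, variances 1 fix the latent scale). The marginal likelihood
integrates each person's response probabilities over this population.

**Quadrature EM** (up to four traits): E-step posterior weights on an
equidistant tensor grid, 21 points per dimension on [-6, 6] by default
(the rectangle rule is within 5e-3 of a 201-point reference on desk
problems; pass `n_quad=61` for 1e-4 agreement). M-step: per-block damped
Newton with analytic gradients and Hessians of the weighted complete-data
log-likelihood; `R` is updated from posterior second moments, rescaled to
unit diagonal and projected to the positive-definite cone (eigenvalue
floor 1e-6). Convergence: maximum absolute parameter change below 1e-4.
The observed log-likelihood is monitored every cycle and is nondecreasing
up to numerical slack.

**MHRM** (any dimension): each cycle advances a persistent random-walk
Metropolis chain on every person's trait posterior (one step per cycle by
default; the proposal scale adapts toward 0.2–0.5 acceptance during
burn-in), then applies a gain-damped Newton update of each block's
parameters using complete-data gradients and a running average of the
complete-data Hessian, and moves `R` toward the sampled traits'
correlation matrix. The gain is 1 during a 150-cycle burn-in and decays
as `t^-0.75` afterwards. Estimates are the tail averages of the final 20
iterates. Convergence requires every per-cycle update to stay below 5e-4
over a 20-cycle window (validated against the quadrature oracle on
two-trait problems: item-parameter discrepancies at most ~0.04); repeated
correlation updates outside the PD cone mark the run nonconverged.
Starting values everywhere: slopes ±1 by keyed sign, intercepts 0,
intertrait correlations 0.25.

Standard errors use the Fisher identity: each person's observed score is
the posterior expectation of the complete-data score (grid weights for
quadrature, thinned MH draws for MHRM), and the information matrix is the
empirical cross-product of these scores; correlation scores come from
`0.5 (P theta theta' P - P)` with `P = R^{-1}`.

The marginal log-likelihood for AIC/BIC uses the quadrature rule up to
four traits and otherwise per-person importance sampling from a Laplace
(normal-at-the-MAP, covariance inflated 1.3x) proposal with 512 draws by
default, deterministic given the seed. AIC = -2 loglik + 2p and
BIC = -2 loglik + p log N with `p` the count of free slopes, free
intercepts, and (unless fixed) the `D(D-1)/2` correlations.

## Bayesian estimation

The sampler targets the joint posterior of item parameters, person
traits, and correlations with the priors: lognormal(0, 2 on the log
scale) on slope magnitudes with signs fixed at the keyed directions,
Normal(0, 3) on free intercepts, LKJ(shape 4) on `R`, and the standard
MVN population on traits. It is an adaptive Metropolis-within-Gibbs
scheme — a deliberate design choice of this package; gradient-based
samplers target the same posterior. Slopes are sampled as log
magnitudes (where the lognormal prior is Gaussian). `R` is sampled
through canonical partial correlations mapped to a Cholesky factor, with
tanh-unconstrained coordinates; under LKJ(eta) the partial correlations
are independent scaled-Beta variables, giving an exact prior in the
sampling space (the closed-form LKJ normalizing constant is verified
against brute-force integration in the tests). Person traits update in a
single vectorized random-walk sweep. All proposal scales adapt toward
30% acceptance during burn-in only.

Defaults are 4 chains of 8000 iterations with 4000 burn-in; estimates
are pooled posterior means, uncertainty pooled posterior SDs, and a run
counts as converged only if every parameter has split R-hat < 1.01 and
bulk effective sample size > 400. Desk-scale chains frequently fail that
strict bar while their posterior means already agree with maximum
likelihood to within a fraction of a posterior SD; nonconvergence is a
reported flag, never an exception.

## Scoring

MAP scores maximize the per-person log posterior by vectorized damped
Newton (analytic gradient and Hessian, gradient tolerance 1e-6), run
from the prior mode and from one perturbed start, keeping the better
mode; failures fall back to EAP with a warning. SEs are square roots of
the inverse negative Hessian diagonal at the mode; with no items
answered this reproduces the prior SDs exactly. EAP (grid up to three
traits, Monte Carlo above) is available as a cross-check. Empirical
reliability of a trait's scores is `V / (V + mean SE^2)` with `V` the
sample variance of the estimates; it is 0 by convention (with a warning)
when the estimates have no variance.

## Fit diagnostics

Model-implied univariate margins and pairwise joint tables integrate
response probabilities over the trait population (20,000 Monte Carlo
draws by default, seeded). Local dependence per block pair: Pearson X²
of observed versus implied joint tables, reported as Cramer's
V = sqrt(X² / (N (min(r,c) - 1))) clipped to [0, 1] and flagged above
0.3; sparse tables are first collapsed by repeatedly merging the two
smallest-margin rows (or columns) of the dimension holding the smallest
expected cell, never below 2x2. Item fit: the standardized item
log-likelihood z = (L - E[L]) / sqrt(Var[L]) with moments taken under
the fitted model at each person's MAP score, flagged below -1.64 (lower
one-sided); this package's choice of statistic, recorded in the output
metadata. SRMSR is the root mean square of
`(p_obs - p_exp) / sqrt(p_exp (1 - p_exp))` over all univariate margins
and bivariate cells; its sampling floor scales as `1/sqrt(N)`, so
close-fit comparisons (< 0.027) are meaningful at a few thousand persons
and above. Item trait characteristic curves average the focal
statement's expected rank score over the non-focal traits with
normalized MVN weights on a 31-point grid per trait on [-3, 3]; with
correlated traits these *marginal* curves can decrease even for positive
slopes (the competitors' conditional means rise with the focal trait) —
the always-monotone quantity is the expected score with the other traits
held fixed.

## Synthetic studies

The generator reproduces the crossed simulation design the package is
validated on: 1000 test takers; 5 traits, 12 statements each, assembled
as two repetitions of the ten 3-of-5 trait combinations (20 triplets) or
three repetitions of the five 4-of-5 combinations (15 tetrads); slope
magnitudes lognormal with natural-scale mean 0.64 / 1.28 / 2.0 (low /
medium / high) and natural-scale SD 0.29, moment-matched on the log
scale; intercepts Normal(-0.05, 0.54) with the first per block fixed to
0; keyed directions either all-same (first half of blocks positive,
second half negative: 10/10 triplets, 8/7 tetrads) or mixed (one
statement flipped in ten of the twenty triplets, balanced so each trait
flips once among positive and once among negative items — assigned
deterministically by a greedy pass over the block order — or the last
two statements flipped in tetrad items 1–3 and 12–15). Item and person
parameters are redrawn every replicate.

The default intertrait correlation matrix has off-diagonals 0.10–0.55 in
steps of 0.05, arranged in a banded decaying pattern and verified
positive definite at construction; heterogeneous true values keep
"correlation with truth" summaries well defined, and the matrix is fully
user-overridable.

What the generator does *not* emulate: response distortion (faking),
nonresponse beyond the structural missingness of PICK/MOLE, person
misfit, or local dependence between blocks. Passing recovery tests
therefore demonstrate internal consistency of model, sampler, and
estimators under correctly specified data — not robustness to the
violations real questionnaires can contain.

## Problem sizes and numerical choices

The test suite and the acceptance script run study-scale fits (n = 1000,
20 triplets, 5 traits) by MHRM and desk-scale cross-checks (2 traits,
4–9 blocks) by quadrature, sizes chosen to exercise every code path
while a full run stays in the minutes range on one core. Probabilities
are floored at 1e-300 before logs; softmax uses max-subtraction;
correlation matrices are kept PD by spectral clipping; Newton steps are
clipped (0.5 in MHRM) and step-halved (EM, scoring) to guarantee ascent.

## Known limitations

* The sequential baseline stops at triplets; larger-block rank baselines
  and Thurstonian pairwise models are out of scope.
* Estimation covers the primary scoring scheme; the alternative
  rank-intercept scheme is modelled but not fitted.
* Limited-information omnibus statistics (M2-type, RMSEA) are not
  implemented; SRMSR plus the pairwise and item-level screens above are
  the fit surface.
* MHRM convergence detection is heuristic (small-update window); badly
  identified problems (e.g. all-same keyed directions with low slopes)
  can freeze short of the MLE, mirroring the practical difficulty of
  those designs.
* The Metropolis-within-Gibbs sampler needs long chains for the strict
  R-hat/ESS bar on person-heavy problems; it prioritizes correctness and
  transparency over sampling efficiency.
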