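# Methods

## Model

Each subject *i* contributes K longitudinal outcome series and one
right-censored event time (T_i, delta_i). The longitudinal sub-model is the
multivariate Laird-Ware linear mixed model

    y_i | b_i ~ N(X_i beta + Z_i b_i, Sigma_i),    b_i ~ N(0, D),

where `X_i` and `Z_i` are outcome-major direct sums of the per-outcome
design matrices, `Sigma_i` is diagonal with per-outcome residual variances
sigma_k^2, and `D` is an unstructured r x r covariance (r = sum r_k) whose
off-diagonal blocks couple the outcomes. The hazard sub-model is
semiparametric proportional hazards,

    lambda_i(t) = lambda_0(t) exp{ v_i' gamma_v + sum_k gamma_yk z_ik(t)' b_ik },

with `lambda_0` a nonparametric baseline whose mass sits at the distinct
observed failure times (Breslow/NPMLE treatment: the cumulative hazard is a
step-sum over those atoms). Conditional on b_i the two processes are
independent; censoring and visit times are assumed non-informative (no
diagnostic for this assumption is provided). Survival covariates v_i are
baseline-only. Stationary-process components and frailty terms in the
hazard, competing risks, and dynamic prediction are out of scope.

Because the hazard evaluates z_ik(t) at event times that need not coincide
with measurement times, a column-based data interface needs an evaluation
rule: each random-effects covariate must be either the time column itself
or constant within subject (the intercept being the common case). Columns
violating this are rejected at load time. Measurements recorded after the
observed event/censoring time are retained with a warning (the likelihood
conditions on all of y_i); duplicate (id, time) rows within an outcome are
an error rather than averaged, since silent aggregation would change
Sigma_i. Missing responses or covariates drop the row with a warning.

## Estimation

Parameters theta = (beta, vech(D), sigma^2, gamma_v, gamma_y, lambda_0) are
estimated by Monte Carlo EM, treating b_i as missing data.

**E-step.** The posterior of b_i given the longitudinal data alone is
normal with covariance A_i = (Z_i' Sigma_i^-1 Z_i + D^-1)^-1 and mean
A_i Z_i' Sigma_i^-1 (y_i - X_i beta). N draws are taken antithetically:
N/2 standard normal vectors Omega give pairs mean +/- C_i Omega with
C_i C_i' = A_i, so each pair averages exactly to the posterior mean and
variances of monotone functionals shrink. Draws are reweighted by the
survival density f(T_i, delta_i | b; theta) (computed on the log scale and
max-shifted before exponentiation), giving self-normalised importance
estimates of every conditional expectation the M-step needs. Draws are
refreshed every iteration; no recycling across iterations.

**M-step.** Closed form for the longitudinal parameters:
beta_k = (sum X_ik'X_ik)^-1 sum X_ik'(y_ik - Z_ik E[b_ik]) (the
block-diagonal design makes the residual variance drop out), sigma_k^2 from
the expected squared residuals at the new beta_k plus the trace correction
tr(Z_ik Var[b_ik] Z_ik'), and D = n^-1 sum E[b_i b_i'] (symmetrised, with
an eigenvalue floor of 1e-10 against Monte Carlo rounding). The baseline
hazard update is the Breslow estimator lambda_0j = d_j / sum_{T_i >= t_j}
E[exp(v_i'gamma_v + W_2i(t_j, b))], evaluated with the E-step expectations
as computed (i.e. paired with the gamma those expectations used; with
one-step gamma updates no component is exactly maximised per iteration and
the one-iteration lag vanishes at convergence). The gamma block takes a
single Newton-Raphson step gamma + I^-1 S using the observed information of
the expected complete-data log-likelihood on the frozen expectations, or
optionally a Gauss-Newton-like step of size 0.5 using the empirical
information sum s_i s_i' - (1/n) S S'. Both the score and the NR
information are validated in the test suite against brute-force
finite differences on frozen draws.

**Initial values.** Separate per-outcome linear mixed models are fitted by
closed-form EM (maximum likelihood, not REML — the joint likelihood is an
ML construction), then a multivariate LMM EM starting from the
block-diagonal D refines (beta, D, sigma^2) under a stricter tolerance
(absolute max change < 1e-6; the EM and its monotone marginal likelihood
are exposed for testing). For the hazard: when visit times are balanced
across outcomes, each subject's BLUP linear predictor z_ik(t)' bhat_ik is
evaluated at every distinct failure time and entered as a left-continuous
step time-varying covariate in a Cox model (Breslow ties, counting-process
rows, Newton-Raphson with step-halving) next to v_i; its coefficients start
(gamma_v, gamma_y). With unbalanced data the Cox model uses v_i only and
gamma_y starts at zero, as does the fallback when the two-stage fit
separates. The initial baseline hazard is the Breslow estimator with W_2
plugged in at the BLUPs.

**Convergence and Monte Carlo size.** Convergence is declared on
theta_{-lambda} = (beta, vech(D), sigma^2, gamma) — the baseline hazard is
profiled and excluded. The default criterion is hybrid: components with
current magnitude >= 0.01 are checked by relative change
|Delta|/(|theta| + eps1) < eps0, near-zero components by absolute change
< eps2 (defaults eps0 = eps2 = 0.005, eps1 = 0.001). A pure relative rule
is also available but cannot terminate when true parameters are zero, as in
the reference simulation design, because the relative change of those
components is Monte Carlo noise; pure absolute is available too. The rule
must pass on 3 consecutive iterations. The Monte Carlo size starts at
N0 = 100K (after a burn-in of 100K iterations at fixed N0, with K the
number of outcomes) and grows by N := N + floor(N/delta), delta = 3
(rounded up to even for antithetic pairing), whenever the coefficient of
variation of the last three relative differences exceeds that of the
previous overlapping window. An optional cap `max_N` bounds the growth;
it is unset by default.

**Likelihood and information.** The observed-data log-likelihood is
sum_i log f(y_i) + log N^-1 sum_m f(T_i, delta_i | b_m) with b_m antithetic
posterior draws; f(y_i) is the marginal normal density evaluated through
the Woodbury identity on the same cross-products the E-step uses. AIC/BIC
count p = dim(theta_{-lambda}) only — the profiled baseline hazard is
excluded, a documented choice. Standard errors invert the empirical profile
information I_e = sum_i s_i s_i' - (1/n) S S', where s_i is the conditional
expectation of the complete-data profile score at the maximiser with
lambda_0 replaced by its Breslow estimate, computed from a fresh E-step
with 4x the final Monte Carlo size (capped at 20000) to reduce MC
contamination; the subtracted term is kept because MC error leaves the
total score slightly nonzero. The D-block of the score uses the
half-vectorisation convention (column-major lower triangle), with
off-diagonal entries doubled. These scores are validated against finite
differences of a quadrature observed log-likelihood (Fisher identity).
Like any implicit-profile estimator, these SEs tend to be slightly
underestimated; the bootstrap (resampling subjects with replacement,
relabelling, refitting from the fitted estimates, dropping non-converged
replicates with a count) is the alternative, with percentile intervals.
Neither method reports uncertainty for lambda_0.

## Synthetic data generator

The simulator reproduces the reference study design: n = 200 subjects,
K = 2 outcomes on the visit grid 0..5 with random intercepts and slopes
per outcome; fixed effects (intercept, slope, x1, x2) = (0, 1, 1, 1) and
(0, -1, 0, 0.5); residual variances 0.25; D diagonal
(0.25, 0.04, 0.25, 0.04) except for a -0.125 intercept-intercept
covariance (correlation -0.5) between the outcomes; x1 ~ N(0,1),
x2 ~ Bernoulli(0.5) entering both sub-models; hazard coefficients
gamma_v = (0, 1), gamma_y = (-0.5, 1); Gompertz baseline with shape -3.5
and log-scale 0.25. Event times invert the log-linear cumulative hazard in
closed form (T = log(1 + b u e^-a)/b for hazard exp(a + bt), with +inf
when the hazard plateaus below u); censoring is exponential with rate
0.05, and any subject whose event and censoring times both exceed the last
visit is administratively censored at 5.1. Longitudinal records are
truncated at the observed time. A multivariate-t option (df = 5, scale
matrix chosen so the covariance — not the scale — equals D) provides the
heavy-tailed robustness variant. The generator emulates the balanced-visit,
monotone-dropout structure of clinical biomarker studies; it does not
produce irregular visit times, missing-at-random gaps within follow-up, or
measurement-error structures beyond iid Gaussian noise, so passing tests
speak to the estimator under a correctly specified model, not to
robustness against real-data violations.

## Problem sizes used by the checks

The reference 500-replicate study is summarised here at reduced scale as
the package's standing check: the test suite runs 4 replicates (the
acceptance script 3) of the n = 200 scenario with reduced Monte Carlo
settings (N0 = 100, burn-in 100 iterations, stopping tolerances 0.01,
Monte Carlo size capped, iteration count capped). Replicates that do not
converge under these reduced settings are excluded with a count.
Mean-estimate checks use the Monte-Carlo-error band
3 x (reference empirical SE / sqrt(R)) at the converged replicate count R
actually obtained — the reference study's replication SD is used for the
band because a sample SD over a handful of replicates is far too noisy to
set one — and coverage checks use the exact binomial test at the 99%
level, so the bands widen honestly with fewer replicates rather than being
retuned. Single-fit sanity checks require every estimate within 4 SEs of
truth and that the Newton-Raphson and Gauss-Newton gamma updates agree
within a few stopping-tolerances on the same seed.

## Numerical choices

- Posterior precision matrices are inverted batched; condition numbers
  above 1e12 raise with the offending subject named.
- exp() arguments are clipped at 500 (80 in the float32 E-step fast path);
  overflowing draws receive ~zero weight rather than poisoning sums.
- The heavy (n, N, J) E-step intermediates run in float32; their rounding
  (~1e-5 relative) sits far below the Monte Carlo noise floor at any
  usable N. All small-dimensional accumulations stay float64.
- Subjects are processed in chunks ordered by follow-up time so each chunk
  only touches the baseline-hazard atoms it is at risk for.
- D iterates are symmetrised and eigenvalue-floored at 1e-10 with a
  warning; sigma_k^2 are positive by construction of the M-step.
- Ties in event times are handled by Breslow's approximation everywhere
  (Cox initialisation and the M-step Breslow estimator share conventions).
- Cox Newton-Raphson uses step-halving (max 10) and flags separation when
  a coefficient exceeds 20 in absolute value; a constant covariate raises
  a degenerate-covariate error.
- Seeds: a single numpy Generator drives every draw in a fit; with equal
  seeds and control settings, traces are bit-identical. Study replicates
  and bootstrap refits derive child seeds below 2^31 from the parent
  generator.

## Known limitations

- The relative stopping rule is undefined at true zeros; the hybrid
  default handles this but introduces an absolute-scale tolerance that is
  not scale-invariant.
- Empirical-profile SEs inherit the implicit-profiling underestimation;
  coverage in the reference design is nonetheless close to nominal.
- The Monte Carlo growth rule reacts to noise in the relative-difference
  sequence and can grow N quickly when tolerances are tight; `max_N`
  bounds the cost at the price of a noise floor.
- Gaussian-quadrature E-steps (attractive for r <= 4) are not implemented;
  the Monte Carlo E-step is the scalable general path.
- Time-varying survival covariates beyond the latent association, REML,
  serial correlation and heteroscedastic residuals are not supported.
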