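"""Likelihood evaluation and standard errors for fitted joint models.

The observed-data log-likelihood factorises as

    sum_i [ log f(y_i; theta) + log E_{b|y}[ f(T_i, delta_i | b; theta) ] ],

where f(y_i) is the marginal multivariate normal density of the
longitudinal data and the inner expectation is estimated by antithetic
Monte Carlo over the posterior of the random effects given y_i.

Approximate standard errors come from the observed empirical profile
information

    I_e(theta_{-lambda}) = sum_i s_i s_i' - (1/n) S S',

where s_i is the conditional expectation of the complete-data profile
score for subject i at the maximiser (baseline hazard replaced by its
Breslow estimator) and S = sum_i s_i.  The subtracted term would vanish at
an exact maximiser but is retained because Monte Carlo error leaves the
score slightly nonzero.  Bootstrap standard errors (resampling subjects
with replacement and refitting from the fitted estimates) are the
alternative.  Neither reports uncertainty for the baseline hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .data import FitResult, JointDataset, MCEMControl, ParameterSet, vech

__all__ = [
    "SEResult",
    "observed_loglik",
    "empirical_information_se",
    "bootstrap_se",
    "aic_bic",
    "profile_scores",
]


@dataclass
class SEResult:
    method: str
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    labels: list[str]
    vcov: np.ndarray | None = None
    B: int | None = None
    n_dropped: int = 0


def _as_theta(fit) -> ParameterSet:
    return fit.theta_hat if isinstance(fit, FitResult) else fit


def observed_loglik(theta, dataset: JointDataset, N: int, rng) -> float:
    """Monte Carlo estimate of the observed-data log-likelihood."""
    from .mcem import _JointEngine

    theta = _as_theta(theta)
    engine = _JointEngine(dataset)
    ll = engine.cache.marginal_loglik(theta.beta, theta.D, theta.sigma2)
    if N % 2:
        raise ValueError("N must be even (antithetic pairing)")
    b, _, _ = engine.draw_all(theta, N, rng)
    logw = engine.log_weights(theta, b)
    per_subject = logsumexp(logw, axis=1) - np.log(N)
    if np.any(~np.isfinite(per_subject)):
        i = int(np.flatnonzero(~np.isfinite(per_subject))[0])
        raise ValueError(
            f"degenerate survival weights for subject {dataset.subjects[i].id!r}"
        )
    return float(ll + per_subject.sum())


def profile_scores(theta: ParameterSet, dataset: JointDataset, N: int, rng,
                   lambda0: np.ndarray | None = None) -> tuple[np.ndarray, list[str]]:
    """Per-subject conditional expected complete-data profile scores.

    Components, in order: beta, vech(D), sigma^2, gamma_v, gamma_y.  The
    baseline hazard is profiled out: unless supplied, it is replaced by its
    Breslow estimate under the same fresh E-step expectations.
    """
    from .mcem import _JointEngine

    theta = _as_theta(theta)
    engine = _JointEngine(dataset)
    cache = engine.cache
    exp_ = engine.estep(theta, N, rng, need_ww=False)
    th = theta.copy()
    th.lambda0_times = engine.t_fail
    th.lambda0 = engine.breslow(exp_, th) if lambda0 is None else lambda0

    n, K, r = engine.n, engine.K, engine.r
    p_blocks = cache.p_blocks
    beta_blocks = th.beta_blocks(p_blocks)
    Var = exp_.Ebb - np.einsum("ni,nj->nij", exp_.Eb, exp_.Eb)

    s_beta = np.zeros((n, sum(p_blocks)))
    s_sigma = np.zeros((n, K))
    for k in range(K):
        plo, phi = cache.p_offsets[k], cache.p_offsets[k + 1]
        rlo, rhi = cache.r_offsets[k], cache.r_offsets[k + 1]
        s2 = th.sigma2[k]
        for i, s in enumerate(dataset.subjects):
            if cache.n_k[i, k] == 0:
                continue
            e = s.y[k] - s.X[k] @ beta_blocks[k] - s.Z[k] @ exp_.Eb[i, rlo:rhi]
            s_beta[i, plo:phi] = s.X[k].T @ e / s2
            tr = float(np.sum(cache.ZtZ[k][i] * Var[i, rlo:rhi, rlo:rhi]))
            s_sigma[i, k] = -cache.n_k[i, k] / (2 * s2) + (e @ e + tr) / (
                2 * s2**2
            )

    Dinv = np.linalg.inv(th.D)
    G = 0.5 * (
        np.einsum("ij,njk,kl->nil", Dinv, exp_.Ebb, Dinv) - Dinv[None]
    )
    # vech gradient: off-diagonal entries appear twice in the symmetric matrix
    Gfull = 2 * G - np.einsum("nij,ij->nij", G, np.eye(r))
    s_D = np.array([vech(Gfull[i]) for i in range(n)])

    _, _, s_gamma = engine.gamma_score_info(exp_, th, method="GN")
    scores = np.concatenate([s_beta, s_D, s_sigma, s_gamma], axis=1)
    return scores, th.labels(dataset)


def empirical_information_se(fit, dataset: JointDataset, N: int, rng,
                             level: float = 0.95) -> SEResult:
    """Standard errors from the inverse empirical profile information."""
    theta = _as_theta(fit)
    s_i, labels = profile_scores(theta, dataset, N, rng)
    S = s_i.sum(axis=0)
    I_e = s_i.T @ s_i - np.outer(S, S) / dataset.n
    w = np.linalg.eigvalsh(I_e)
    if w[0] <= 0:
        raise np.linalg.LinAlgError(
            "empirical information not positive definite "
            f"(smallest eigenvalues {w[:3]})"
        )
    vcov = np.linalg.inv(I_e)
    se = np.sqrt(np.diag(vcov))
    z = norm.ppf(0.5 + level / 2)
    est = theta.flat()
    return SEResult(
        method="empirical", se=se, ci_lower=est - z * se, ci_upper=est + z * se,
        labels=labels, vcov=vcov,
    )


def bootstrap_se(fit: FitResult, dataset: JointDataset, B: int,
                 control: MCEMControl, rng, level: float = 0.95) -> SEResult:
    """Bootstrap standard errors: resample subjects with replacement, refit.

    Each replicate relabels the resampled subjects, refits starting from the
    fitted estimates, and contributes its theta_{-lambda}; replicates that
    fail to converge are dropped with a count.  Percentile confidence
    intervals use the empirical alpha/2 and 1 - alpha/2 quantiles.
    """
    from dataclasses import replace as dc_replace

    from .data import SubjectData
    from .mcem import mcem_fit

    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    estimates = []
    n_dropped = 0
    for b_rep in range(B):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        subs = [
            dc_replace(dataset.subjects[i], id=f"b{j}")
            for j, i in enumerate(idx)
        ]
        boot = JointDataset(
            subs, dataset.specs, dataset.survival_covariates, dataset.balanced
        )
        if boot.n_events == 0:
            n_dropped += 1
            continue
        ctl = dc_replace(
            control, se_method="none",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mcem_fit(boot, ctl, init=fit.theta_hat)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            n_dropped += 1
            continue
        if not res.converged:
            n_dropped += 1
            continue
        estimates.append(res.theta_hat.flat())
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} bootstrap replicate(s) dropped (non-convergence)"
        )
    E = np.array(estimates)
    se = E.std(axis=0, ddof=1)
    alpha = 1 - level
    lo = np.percentile(E, 100 * alpha / 2, axis=0)
    hi = np.percentile(E, 100 * (1 - alpha / 2), axis=0)
    return SEResult(
        method="bootstrap", se=se, ci_lower=lo, ci_upper=hi,
        labels=fit.labels, B=len(estimates), n_dropped=n_dropped,
    )


def aic_bic(fit: FitResult, n_subjects: int | None = None) -> tuple[float, float]:
    """AIC and BIC with p = dim(theta_{-lambda}) (profiled baseline excluded)."""
    n = n_subjects if n_subjects is not None else fit.n_subjects
    if n <= 0:
        raise ValueError("number of subjects required for BIC")
    p = len(fit.theta_hat.flat())
    ll = fit.loglik
    return -2 * ll + 2 * p, -2 * ll + p * np.log(n)
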