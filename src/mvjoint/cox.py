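"""Cox proportional hazards fitting by partial likelihood.

Used to seed the joint model's hazard coefficients: a plain Cox fit on the
baseline covariates gives starting values for ``gamma_v``; when visit times
are balanced across outcomes, a quasi-two-stage fit adds the BLUP-predicted
latent trajectories of each outcome as piecewise-constant time-varying
covariates (counting-process rows), whose coefficients start ``gamma_y``.

Ties are handled with Breslow's approximation throughout, matching the
Breslow baseline-hazard estimator used in the joint model M-step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import JointDataset
from .lmm import LMMComponent, REPosteriorMoments, posterior_re_moments

__all__ = ["CoxFit", "coxph_partial_fit", "two_stage_initial_values", "CoxPH"]


@dataclass
class CoxFit:
    gamma: np.ndarray
    loglik: float
    iterations: int
    information: np.ndarray


class _PartialLik:
    """Breslow partial likelihood on counting-process rows (start, stop]."""

    def __init__(self, start, stop, status, X):
        start = np.asarray(start, float)
        stop = np.asarray(stop, float)
        status = np.asarray(status, int)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(stop):
            X = X.T
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values")
        if status.sum() < 1:
            raise ValueError("no events")
        self.X = X
        ev_times = np.unique(stop[status == 1])
        self.t = ev_times
        # risk membership: start < t_j <= stop
        self.mask = (start[:, None] < ev_times[None, :]) & (
            stop[:, None] >= ev_times[None, :]
        )
        ev = (status == 1)[:, None] & (stop[:, None] == ev_times[None, :])
        self.d = ev.sum(axis=0).astype(float)
        self.s = ev.T.astype(float) @ X  # (J, q) sum of event covariates

    def eval(self, gamma):
        eta = self.X @ gamma
        shift = eta.max()  # max-shift before exponentiation; added back in loglik
        w = np.exp(eta - shift)
        W = self.mask * w[:, None]  # (m, J)
        denom = W.sum(axis=0)
        if np.any(denom <= 0):
            raise np.linalg.LinAlgError("empty risk set at a failure time")
        m1 = W.T @ self.X / denom[:, None]  # (J, q) weighted means
        m2 = np.einsum("mj,ma,mb->jab", W, self.X, self.X) / denom[:, None, None]
        loglik = float(
            np.sum(self.s @ gamma) - np.sum(self.d * (np.log(denom) + shift))
        )
        score = self.s.sum(axis=0) - self.d @ m1
        info = np.einsum(
            "j,jab->ab", self.d, m2 - np.einsum("ja,jb->jab", m1, m1)
        )
        return loglik, score, info


def coxph_partial_fit(
    durations,
    status,
    X,
    start=None,
    gamma0=None,
    tol_score: float = 1e-6,
    tol_loglik: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson maximisation of the Breslow partial likelihood.

    ``start`` (optional) turns the rows into counting-process records
    (start, stop] for piecewise-constant time-varying covariates.  Newton
    steps are halved (up to 10 times) whenever they would decrease the
    partial log-likelihood.
    """
    durations = np.asarray(durations, float)
    if start is None:
        start = np.zeros_like(durations)
    pl = _PartialLik(start, durations, status, X)
    q = pl.X.shape[1]
    gamma = np.zeros(q) if gamma0 is None else np.asarray(gamma0, float).copy()
    loglik, score, info = pl.eval(gamma)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "degenerate covariate: singular information in Cox fit"
            ) from err
        factor = 1.0
        for _ in range(10):
            cand = gamma + factor * step
            new_loglik, new_score, new_info = pl.eval(cand)
            if new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        rel_change = abs(new_loglik - loglik) / (abs(loglik) + 1.0)
        gamma, loglik, score, info = cand, new_loglik, new_score, new_info
        if np.max(np.abs(gamma)) > 20:
            # separation flattens the partial likelihood, so the score may
            # vanish while the coefficient diverges; the magnitude is the signal
            raise np.linalg.LinAlgError(
                "separation: Cox coefficient diverging (|gamma| > 20)"
            )
        if np.max(np.abs(score)) < tol_score or rel_change < tol_loglik:
            break
    else:
        warnings.warn("Cox Newton-Raphson reached max_iter")
    return CoxFit(gamma, loglik, it, info)


def blup_random_effects(
    dataset: JointDataset, lmm_fits: list[LMMComponent]
) -> list[list[np.ndarray]]:
    """Per-subject BLUPs of each outcome's random effects under separate fits."""
    from .data import ParameterSet

    out = []
    for s in dataset.subjects:
        per_k = []
        for k, comp in enumerate(lmm_fits):
            theta_k = ParameterSet(
                comp.beta_k, comp.D_kk, np.array([comp.sigma2_k]),
                np.zeros(0), np.zeros(1),
            )
            sub_view = type(s)(
                s.id, [s.times[k]], [s.y[k]], [s.X[k]], [s.Z[k]],
                s.time, s.event, s.v,
                [s.z_const[k]] if s.z_const else [],
            )
            per_k.append(posterior_re_moments(sub_view, theta_k).mean)
        out.append(per_k)
    return out


def two_stage_initial_values(
    dataset: JointDataset, lmm_fits: list[LMMComponent]
) -> tuple[np.ndarray, np.ndarray]:
    """Starting values (gamma_v0, gamma_y0) for the hazard coefficients.

    Balanced data: each subject's BLUP linear predictor z_ik(t)' bhat_ik is
    evaluated at every distinct failure time and entered as a left-continuous
    step time-varying covariate in a Cox model next to the baseline
    covariates.  Unbalanced data: Cox on the baseline covariates only, with
    gamma_y0 = 0.  On separation the fallback is likewise gamma_y0 = 0.
    """
    K, q = dataset.K, dataset.q
    t_fail, _ = dataset.failure_times()
    times = np.array([s.time for s in dataset.subjects])
    status = np.array([s.event for s in dataset.subjects])
    V = np.array([s.v for s in dataset.subjects]).reshape(dataset.n, q)

    def baseline_only():
        if q == 0:
            return np.zeros(0), np.zeros(K)
        fit = coxph_partial_fit(times, status, V)
        return fit.gamma, np.zeros(K)

    if not dataset.balanced or len(t_fail) == 0:
        return baseline_only()

    blups = blup_random_effects(dataset, lmm_fits)
    rows_start, rows_stop, rows_status, rows_X = [], [], [], []
    for i, s in enumerate(dataset.subjects):
        at_risk = t_fail[t_fail <= s.time]
        if len(at_risk) == 0:
            continue
        prev = np.concatenate([[0.0], at_risk[:-1]])
        for t0, tj in zip(prev, at_risk):
            w = [float(s.z_at(k, tj) @ blups[i][k]) for k in range(K)]
            rows_start.append(t0)
            rows_stop.append(tj)
            rows_status.append(int(s.event == 1 and s.time == tj))
            rows_X.append(np.concatenate([s.v, w]))
    try:
        fit = coxph_partial_fit(
            np.array(rows_stop), np.array(rows_status), np.array(rows_X),
            start=np.array(rows_start),
        )
        return fit.gamma[:q], fit.gamma[q:]
    except np.linalg.LinAlgError as err:
        warnings.warn(
            f"two-stage Cox initialisation failed ({err}); "
            "falling back to gamma_y0 = 0"
        )
        return baseline_only()


class CoxPH(BaseEstimator):
    """Cox proportional hazards model (Breslow ties, Newton-Raphson).

    Supports counting-process rows via the ``start`` argument of
    :meth:`fit` for piecewise-constant time-varying covariates.
    """

    def __init__(self, tol_score: float = 1e-6, tol_loglik: float = 1e-9,
                 max_iter: int = 50):
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik
        self.max_iter = max_iter

    def fit(self, X, durations, status, start=None):
        res = coxph_partial_fit(
            durations, status, X, start=start,
            tol_score=self.tol_score, tol_loglik=self.tol_loglik,
            max_iter=self.max_iter,
        )
        self.coef_ = res.gamma
        self.loglik_ = res.loglik
        self.n_iter_ = res.iterations
        self.information_ = res.information
        return self
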