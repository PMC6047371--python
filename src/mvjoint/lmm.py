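"""Linear mixed models for the longitudinal sub-model.

Implements the multivariate Laird-Ware model

    y_i | b_i ~ N(X_i beta + Z_i b_i, Sigma_i),   b_i ~ N(0, D),

with ``X_i``, ``Z_i`` outcome-major direct sums and ``Sigma_i`` diagonal
with per-outcome residual variances.  Everything here is maximum likelihood
(not REML): these estimates seed the joint-model MCEM run, whose likelihood
is an ML construction, and the posterior moments of ``b_i`` given the
longitudinal data are the proposal distribution of its Monte Carlo E-step.

The EM updates are closed form: with posterior moments E[b_i] and
Var[b_i] = A_i computed at the current parameters,

    beta_k  <- (sum_i X_ik'X_ik)^-1 sum_i X_ik'(y_ik - Z_ik E[b_ik])
    sigma_k^2 <- (sum_i ||y_ik - X_ik beta_k - Z_ik E[b_ik]||^2
                  + sum_i tr(Z_ik A_i,kk Z_ik')) / sum_i n_ik
    D       <- (1/n) sum_i (A_i + E[b_i]E[b_i]')

(the beta update has no sigma dependence because X_i is block diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import JointDataset, OutcomeSpec, ParameterSet, SubjectData, vech

__all__ = [
    "LMMComponent",
    "REPosteriorMoments",
    "fit_univariate_lmm",
    "mvlmm_em",
    "posterior_re_moments",
    "marginal_longitudinal_loglik",
    "UnivariateLMM",
    "MultivariateLMM",
]

_SPD_FLOOR = 1e-10


@dataclass
class LMMComponent:
    """Parameters of one outcome's separate linear mixed model."""

    beta_k: np.ndarray
    D_kk: np.ndarray
    sigma2_k: float


@dataclass
class REPosteriorMoments:
    """Posterior mean/covariance of b_i given the longitudinal data only."""

    mean: np.ndarray
    cov: np.ndarray
    chol: np.ndarray


def _spd_floor(M: np.ndarray, floor: float = _SPD_FLOOR, warn: bool = True) -> np.ndarray:
    """Symmetrize and floor eigenvalues so iterates stay usable as covariances."""
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w[0] < floor:
        if warn:
            warnings.warn(
                f"covariance iterate at boundary (min eigenvalue {w[0]:.2e}); "
                "flooring"
            )
        w = np.maximum(w, floor)
        M = (V * w) @ V.T
        M = (M + M.T) / 2.0
    return M


class DesignCache:
    """Pre-computed per-subject cross-products for fast repeated E-steps.

    Crossproducts are stored per outcome block; the block-diagonal structure
    of ``X_i`` and ``Z_i`` means all full-dimension quantities assemble from
    these without ever forming the stacked matrices.
    """

    def __init__(self, dataset: JointDataset):
        self.dataset = dataset
        self.n = dataset.n
        self.K = dataset.K
        self.p_blocks = dataset.p_blocks
        self.r_blocks = dataset.r_blocks
        self.r = dataset.r
        self.r_offsets = np.concatenate([[0], np.cumsum(self.r_blocks)])
        self.p_offsets = np.concatenate([[0], np.cumsum(self.p_blocks)])
        # per outcome: arrays over subjects
        self.ZtZ = []  # (n, r_k, r_k)
        self.Zty = []  # (n, r_k)
        self.ZtX = []  # (n, r_k, p_k)
        self.XtX = []  # (p_k, p_k) summed over subjects
        self.XtX_i = []  # (n, p_k, p_k)
        self.Xty = []  # (n, p_k)
        self.n_k = np.zeros((self.n, self.K), dtype=int)
        self.yty = np.zeros((self.n, self.K))
        for k in range(self.K):
            rk, pk = self.r_blocks[k], self.p_blocks[k]
            ZtZ = np.zeros((self.n, rk, rk))
            Zty = np.zeros((self.n, rk))
            ZtX = np.zeros((self.n, rk, pk))
            XtX_i = np.zeros((self.n, pk, pk))
            Xty = np.zeros((self.n, pk))
            for i, s in enumerate(dataset.subjects):
                Z, X, y = s.Z[k], s.X[k], s.y[k]
                self.n_k[i, k] = len(y)
                if len(y) == 0:
                    continue
                ZtZ[i] = Z.T @ Z
                Zty[i] = Z.T @ y
                ZtX[i] = Z.T @ X
                XtX_i[i] = X.T @ X
                Xty[i] = X.T @ y
                self.yty[i, k] = y @ y
            self.ZtZ.append(ZtZ)
            self.Zty.append(Zty)
            self.ZtX.append(ZtX)
            self.XtX_i.append(XtX_i)
            self.XtX.append(XtX_i.sum(axis=0))
            self.Xty.append(Xty)
        self.total_n_k = self.n_k.sum(axis=0)

    def _c_vector(self, beta_blocks, sigma2) -> np.ndarray:
        """c_i = Z_i' Sigma_i^-1 (y_i - X_i beta), stacked (n, r)."""
        c = np.zeros((self.n, self.r))
        for k in range(self.K):
            lo, hi = self.r_offsets[k], self.r_offsets[k + 1]
            c[:, lo:hi] = (self.Zty[k] - self.ZtX[k] @ beta_blocks[k]) / sigma2[k]
        return c

    def _a_inv(self, D, sigma2) -> np.ndarray:
        """A_i^-1 = Z_i'Sigma_i^-1 Z_i + D^-1, stacked (n, r, r)."""
        Dinv = np.linalg.inv(D)
        A_inv = np.broadcast_to(Dinv, (self.n, self.r, self.r)).copy()
        for k in range(self.K):
            lo, hi = self.r_offsets[k], self.r_offsets[k + 1]
            A_inv[:, lo:hi, lo:hi] += self.ZtZ[k] / sigma2[k]
        return A_inv

    def posterior_moments(self, beta, D, sigma2):
        """Batched posterior moments (mean (n,r), cov (n,r,r), chol (n,r,r))."""
        beta_blocks = _split(beta, self.p_blocks)
        A_inv = self._a_inv(D, sigma2)
        cond = np.linalg.cond(A_inv)
        if np.any(cond > 1e12):
            i = int(np.argmax(cond))
            raise np.linalg.LinAlgError(
                f"posterior precision numerically singular for subject "
                f"{self.dataset.subjects[i].id!r} (condition number {cond[i]:.2e})"
            )
        A = np.linalg.inv(A_inv)
        A = (A + np.transpose(A, (0, 2, 1))) / 2.0
        c = self._c_vector(beta_blocks, sigma2)
        mean = np.einsum("nij,nj->ni", A, c)
        chol = np.linalg.cholesky(A)
        return mean, A, chol

    def marginal_loglik(self, beta, D, sigma2) -> float:
        """sum_i log N(y_i; X_i beta, Sigma_i + Z_i D Z_i') via the Woodbury identity."""
        beta_blocks = _split(beta, self.p_blocks)
        A_inv = self._a_inv(D, sigma2)
        sign, logdet_Ainv = np.linalg.slogdet(A_inv)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-SPD marginal covariance")
        signD, logdetD = np.linalg.slogdet(D)
        if signD <= 0:
            raise np.linalg.LinAlgError("D is not positive definite")
        c = self._c_vector(beta_blocks, sigma2)
        A = np.linalg.inv(A_inv)
        quad_corr = np.einsum("ni,nij,nj->n", c, A, c)
        # residual quadratic form e'Sigma^-1 e per subject
        quad = np.zeros(self.n)
        logdet_Sigma = np.zeros(self.n)
        ntot = self.n_k.sum(axis=1)
        for k in range(self.K):
            bk = beta_blocks[k]
            quad += (
                self.yty[:, k]
                - 2 * self.Xty[k] @ bk
                + np.einsum("i,nij,j->n", bk, self.XtX_i[k], bk)
            ) / sigma2[k]
            logdet_Sigma += self.n_k[:, k] * np.log(sigma2[k])
        total = -0.5 * (
            ntot * np.log(2 * np.pi)
            + logdet_Sigma
            + logdetD
            + logdet_Ainv
            + quad
            - quad_corr
        )
        return float(np.sum(total[ntot > 0]))


def _split(vec, blocks):
    out, pos = [], 0
    for b in blocks:
        out.append(np.asarray(vec[pos : pos + b], dtype=float))
        pos += b
    return out


def posterior_re_moments(subject: SubjectData, theta: ParameterSet,
                         r_blocks=None, p_blocks=None) -> REPosteriorMoments:
    """Posterior N(mean, cov) of b_i given this subject's longitudinal data.

    A subject with no measurements gets the prior: mean 0, cov D.
    """
    D = theta.D
    r = D.shape[0]
    if r_blocks is None:
        r_blocks = [Z.shape[1] for Z in subject.Z]
    if p_blocks is None:
        p_blocks = [X.shape[1] for X in subject.X]
    beta_blocks = _split(theta.beta, p_blocks)
    Dinv = np.linalg.inv(D)
    A_inv = Dinv.copy()
    c = np.zeros(r)
    ro = np.concatenate([[0], np.cumsum(r_blocks)])
    for k, (Z, X, y) in enumerate(zip(subject.Z, subject.X, subject.y)):
        if len(y) == 0:
            continue
        lo, hi = ro[k], ro[k + 1]
        A_inv[lo:hi, lo:hi] += (Z.T @ Z) / theta.sigma2[k]
        c[lo:hi] = Z.T @ (y - X @ beta_blocks[k]) / theta.sigma2[k]
    if np.linalg.cond(A_inv) > 1e12:
        raise np.linalg.LinAlgError(
            f"posterior precision numerically singular "
            f"(condition number {np.linalg.cond(A_inv):.2e})"
        )
    cov = np.linalg.inv(A_inv)
    cov = (cov + cov.T) / 2.0
    return REPosteriorMoments(cov @ c, cov, np.linalg.cholesky(cov))


def marginal_longitudinal_loglik(dataset: JointDataset, beta, D, sigma2) -> float:
    """Marginal normal log-likelihood of the longitudinal data."""
    return DesignCache(dataset).marginal_loglik(
        np.asarray(beta, float), np.asarray(D, float), np.asarray(sigma2, float)
    )


def _em_mstep(cache: DesignCache, mean, A):
    """Closed-form M-step given posterior moments (returns beta, sigma2, D)."""
    beta_blocks = []
    sigma2 = np.zeros(cache.K)
    for k in range(cache.K):
        lo, hi = cache.r_offsets[k], cache.r_offsets[k + 1]
        Eb_k = mean[:, lo:hi]
        rhs = cache.Xty[k].sum(axis=0) - np.einsum(
            "nrp,nr->p", cache.ZtX[k], Eb_k
        )
        try:
            bk = np.linalg.solve(cache.XtX[k], rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular fixed-effects system for outcome {k + 1}"
            ) from err
        beta_blocks.append(bk)
        rss = float(
            np.sum(cache.yty[:, k])
            - 2 * cache.Xty[k].sum(axis=0) @ bk
            + bk @ cache.XtX[k] @ bk
            - 2 * np.einsum("nr,nr->", cache.Zty[k], Eb_k)
            + 2 * np.einsum("nr,nrp,p->", Eb_k, cache.ZtX[k], bk)
            + np.einsum("nr,nrs,ns->", Eb_k, cache.ZtZ[k], Eb_k)
        )
        tr = float(np.einsum("nij,nij->", cache.ZtZ[k], A[:, lo:hi, lo:hi]))
        sigma2[k] = (rss + tr) / cache.total_n_k[k]
    Ebb = A + np.einsum("ni,nj->nij", mean, mean)
    D = _spd_floor(Ebb.mean(axis=0))
    return np.concatenate(beta_blocks), sigma2, Ebb, D


def mvlmm_em(
    dataset: JointDataset,
    init: list[LMMComponent] | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
    track_loglik: bool = False,
):
    """EM for the multivariate linear mixed model.

    ``init`` supplies separate single-outcome fits (D initialized
    block-diagonal, off-blocks zero); when omitted they are computed first.
    Convergence is absolute max parameter change < ``tol``.  Returns
    ``(beta, D, sigma2, info)`` with the final (non-block-diagonal) D.
    """
    if dataset.K == 1 and init is None:
        comp, info = _univariate_em(dataset, 0, tol, max_iter)
        return comp.beta_k, comp.D_kk, np.array([comp.sigma2_k]), info
    if init is None:
        init = [fit_univariate_lmm(dataset, k, tol=tol) for k in range(dataset.K)]
    cache = DesignCache(dataset)
    from scipy.linalg import block_diag

    beta = np.concatenate([c.beta_k for c in init])
    D = _spd_floor(block_diag(*[c.D_kk for c in init]), warn=False)
    sigma2 = np.array([c.sigma2_k for c in init], dtype=float)
    info = {"converged": False, "n_iter": 0, "loglik": None, "loglik_history": []}
    for it in range(1, max_iter + 1):
        mean, A, _ = cache.posterior_moments(beta, D, sigma2)
        if track_loglik:
            info["loglik_history"].append(cache.marginal_loglik(beta, D, sigma2))
        beta_new, sigma2_new, _, D_new = _em_mstep(cache, mean, A)
        delta = max(
            np.max(np.abs(beta_new - beta)),
            np.max(np.abs(vech(D_new) - vech(D))),
            np.max(np.abs(sigma2_new - sigma2)),
        )
        beta, D, sigma2 = beta_new, D_new, sigma2_new
        info["n_iter"] = it
        if delta < tol:
            info["converged"] = True
            break
    else:
        warnings.warn(f"multivariate LMM EM reached max_iter={max_iter}")
    info["loglik"] = cache.marginal_loglik(beta, D, sigma2)
    return beta, D, sigma2, info


def _single_outcome_view(dataset: JointDataset, k: int) -> JointDataset:
    spec = dataset.specs[k]
    subs = [
        SubjectData(
            s.id, [s.times[k]], [s.y[k]], [s.X[k]], [s.Z[k]],
            s.time, s.event, s.v, [s.z_const[k]] if s.z_const else [],
        )
        for s in dataset.subjects
    ]
    return JointDataset(subs, [spec], dataset.survival_covariates, True)


def _univariate_em(dataset: JointDataset, k: int, tol: float, max_iter: int):
    sub = dataset if dataset.K == 1 else _single_outcome_view(dataset, k)
    spec = sub.specs[0]
    cache = DesignCache(sub)
    n_total = int(cache.total_n_k[0])
    if n_total < spec.p + spec.r:
        raise ValueError(
            f"outcome {spec.name!r}: {n_total} measurements cannot identify "
            f"{spec.p} fixed effects and {spec.r} random-effect variance terms"
        )
    # start from OLS with an even residual split between D and sigma^2
    ally = np.concatenate([s.y[0] for s in sub.subjects])
    allX = np.vstack([s.X[0] for s in sub.subjects if len(s.y[0])])
    if np.linalg.matrix_rank(allX) < spec.p:
        raise np.linalg.LinAlgError(f"outcome {spec.name!r}: singular fixed design")
    beta = np.linalg.lstsq(allX, ally, rcond=None)[0]
    resid_var = float(np.var(ally - allX @ beta)) or 1.0
    sigma2 = np.array([max(resid_var / 2, 1e-6)])
    D = np.eye(spec.r) * max(resid_var / 2, 1e-6)
    info = {"converged": False, "n_iter": 0, "loglik": None, "loglik_history": []}
    for it in range(1, max_iter + 1):
        mean, A, _ = cache.posterior_moments(beta, D, sigma2)
        beta_new, sigma2_new, _, D_new = _em_mstep(cache, mean, A)
        delta = max(
            np.max(np.abs(beta_new - beta)),
            np.max(np.abs(vech(D_new) - vech(D))),
            np.max(np.abs(sigma2_new - sigma2)),
        )
        beta, D, sigma2 = beta_new, D_new, sigma2_new
        info["n_iter"] = it
        if delta < tol:
            info["converged"] = True
            break
    else:
        warnings.warn(f"univariate LMM EM reached max_iter={max_iter}")
    info["loglik"] = cache.marginal_loglik(beta, D, sigma2)
    return LMMComponent(beta, D, float(sigma2[0])), info


def fit_univariate_lmm(
    dataset: JointDataset, k: int, tol: float = 1e-6, max_iter: int = 5000
) -> LMMComponent:
    """Maximum-likelihood fit of the single-outcome Laird-Ware model (EM)."""
    comp, _ = _univariate_em(dataset, k, tol, max_iter)
    return comp


class UnivariateLMM(BaseEstimator):
    """Single-outcome linear mixed model fitted by maximum likelihood.

    Parameters
    ----------
    outcome : int
        Index of the outcome within the dataset.
    tol : float
        Absolute max-change EM stopping tolerance.
    max_iter : int
        EM iteration cap.
    """

    def __init__(self, outcome: int = 0, tol: float = 1e-6, max_iter: int = 5000):
        self.outcome = outcome
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, dataset: JointDataset, y=None):
        comp, info = _univariate_em(dataset, self.outcome, self.tol, self.max_iter)
        self.beta_ = comp.beta_k
        self.D_ = comp.D_kk
        self.sigma2_ = comp.sigma2_k
        self.loglik_ = info["loglik"]
        self.n_iter_ = info["n_iter"]
        self.converged_ = info["converged"]
        return self


class MultivariateLMM(BaseEstimator):
    """Multivariate linear mixed model fitted by closed-form EM.

    The fitted covariance ``D_`` couples random effects across outcomes;
    initialisation is from separate per-outcome fits with a block-diagonal D.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 5000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, dataset: JointDataset, y=None):
        beta, D, sigma2, info = mvlmm_em(
            dataset, tol=self.tol, max_iter=self.max_iter
        )
        self.beta_ = beta
        self.D_ = D
        self.sigma2_ = sigma2
        self.loglik_ = info["loglik"]
        self.n_iter_ = info["n_iter"]
        self.converged_ = info["converged"]
        return self

    def posterior_moments(self, dataset: JointDataset):
        mean, A, chol = DesignCache(dataset).posterior_moments(
            self.beta_, self.D_, self.sigma2_
        )
        return mean, A, chol
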