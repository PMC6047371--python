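"""Monte Carlo EM engine for the multivariate joint model.

The E-step draws antithetic samples from the posterior of the random
effects given the longitudinal data, N(A_i Z_i'Sigma_i^-1(y_i - X_i beta),
A_i) with A_i = (Z_i'Sigma_i^-1 Z_i + D^-1)^-1, and reweights them by the
survival density

    f(T_i, d_i | b; theta) = [lambda_0(T_i) exp{v_i'g_v + W_2i(T_i,b)}]^d_i
                             * exp{-sum_{t_j <= T_i} lambda_0j
                                    exp(v_i'g_v + W_2i(t_j,b))},

where W_2i(t,b) = sum_k g_yk z_ik(t)' b_ik and the cumulative hazard is the
Breslow step-sum over the distinct observed failure times (the
nonparametric baseline has atoms only there).  Conditional expectations of
any h(b) are then self-normalised importance averages over the draws.

The M-step is closed form for beta, sigma^2, D and the Breslow baseline
increments; gamma = (gamma_v, gamma_y) takes a single Newton-Raphson step
(or a Gauss-Newton-like step of size 0.5 using the empirical information).
Monitoring uses relative/absolute parameter changes excluding the baseline
hazard, with a coefficient-of-variation rule that grows the Monte Carlo
size N := N + floor(N/delta) when the relative-change sequence gets
noisier, after a burn-in of fixed N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import (
    FitResult,
    JointDataset,
    MCEMControl,
    ParameterSet,
    SubjectData,
    validate_dataset,
    vech,
)
from .lmm import (
    DesignCache,
    LMMComponent,
    REPosteriorMoments,
    _em_mstep,
    fit_univariate_lmm,
    mvlmm_em,
)
from .cox import two_stage_initial_values

__all__ = [
    "MCDraws",
    "EStepExpectations",
    "ConvergenceState",
    "draw_antithetic",
    "survival_log_weight",
    "conditional_expectation",
    "mstep_beta_sigma_D",
    "mstep_baseline_hazard",
    "gamma_score_information",
    "gamma_onestep_update",
    "convergence_check",
    "adapt_mc_size",
    "mcem_fit",
    "MultivariateJointModel",
]

_EXP_CLIP = 500.0  # caps exp() arguments; overflowing draws get ~zero weight anyway


# ---------------------------------------------------------------------------
# single-subject primitives (also the reference path used by the oracles)
# ---------------------------------------------------------------------------


@dataclass
class MCDraws:
    """Antithetic Monte Carlo draws for one subject.

    Rows are arranged as pairs (2j, 2j+1) = mean +/- C_i Omega_j, so each
    consecutive pair averages exactly to the posterior mean.
    """

    draws: np.ndarray  # (N, r)
    log_weights: np.ndarray | None = None  # log f(T_i, d_i | b; theta)

    @property
    def N(self) -> int:
        return self.draws.shape[0]

    def weights(self) -> np.ndarray:
        """Normalised weights, computed with a max-shift before exponentiation."""
        if self.log_weights is None:
            return np.full(self.N, 1.0 / self.N)
        m = np.max(self.log_weights)
        if not np.isfinite(m):
            raise ValueError("degenerate survival weights: all log-weights -inf")
        w = np.exp(self.log_weights - m)
        return w / w.sum()


def draw_antithetic(moments: REPosteriorMoments, N: int, rng) -> MCDraws:
    """Draw N antithetic samples mean +/- C_i Omega with C_i C_i' = cov."""
    if N % 2:
        raise ValueError("N must be even for antithetic pairing")
    r = len(moments.mean)
    omega = rng.standard_normal((N // 2, r))
    shift = omega @ moments.chol.T
    draws = np.empty((N, r))
    draws[0::2] = moments.mean + shift
    draws[1::2] = moments.mean - shift
    return MCDraws(draws)


def survival_log_weight(b: np.ndarray, subject: SubjectData, theta: ParameterSet) -> float:
    """log f(T_i, delta_i | b; theta) with the Breslow step cumulative hazard."""
    b = np.asarray(b, float)
    t0 = theta.lambda0_times
    lam = theta.lambda0
    r_blocks = [Z.shape[1] for Z in subject.Z]
    ro = np.concatenate([[0], np.cumsum(r_blocks)])
    K = len(r_blocks)

    def W2(t):
        return sum(
            theta.gamma_y[k] * float(subject.z_at(k, t) @ b[ro[k] : ro[k + 1]])
            for k in range(K)
        )

    base = float(subject.v @ theta.gamma_v) if len(theta.gamma_v) else 0.0
    atoms = t0[t0 <= subject.time] if t0.size else np.array([])
    cum = 0.0
    for t_j, l_j in zip(atoms, lam[: len(atoms)]):
        cum += l_j * np.exp(min(base + W2(t_j), _EXP_CLIP))
    out = -cum
    if subject.event == 1:
        j = np.searchsorted(t0, subject.time)
        if j >= len(t0) or t0[j] != subject.time:
            raise ValueError(
                f"subject {subject.id!r}: event time {subject.time} is not a "
                "baseline-hazard atom"
            )
        out += np.log(lam[j]) + base + W2(subject.time)
    return float(out)


def conditional_expectation(h, draws: MCDraws):
    """Self-normalised weighted average of h(b) over the MC draws."""
    w = draws.weights()
    vals = np.array([np.asarray(h(b), dtype=float) for b in draws.draws])
    return np.tensordot(w, vals, axes=(0, 0))


# ---------------------------------------------------------------------------
# batched E-step
# ---------------------------------------------------------------------------


@dataclass
class EStepExpectations:
    """Per-subject conditional expectations needed by the M-step.

    ``EexpW2*`` arrays are conditional expectations of exp(W_2i(t_j, b))
    times powers of the association covariates w_i(t_j, b) (the K-vector
    with entries z_ik(t_j)'b_ik), already masked to t_j <= T_i; the
    baseline-covariate factor exp(v_i'gamma_v) is applied separately.
    """

    Eb: np.ndarray  # (n, r)
    Ebb: np.ndarray  # (n, r, r)
    EexpW2: np.ndarray  # (n, J)
    EexpW2w: np.ndarray  # (n, J, K)
    EexpW2ww: np.ndarray  # (n, J, K, K)
    Ew_T: np.ndarray  # (n, K), association covariates at T_i (event subjects)
    draws: np.ndarray  # (n, N, r)
    weights: np.ndarray  # (n, N) normalised
    N: int


class _JointEngine:
    """Vectorised E-step/M-step machinery bound to one dataset."""

    def __init__(self, dataset: JointDataset):
        self.dataset = dataset
        self.cache = DesignCache(dataset)
        self.n, self.K, self.r = dataset.n, dataset.K, dataset.r
        self.q = dataset.q
        self.r_offsets = self.cache.r_offsets
        self.t_fail, self.d = dataset.failure_times()
        self.J = len(self.t_fail)
        T = np.array([s.time for s in dataset.subjects])
        self.T = T
        self.delta = np.array([s.event for s in dataset.subjects], dtype=float)
        self.V = np.array([s.v for s in dataset.subjects]).reshape(self.n, self.q)
        self.mask = T[:, None] >= self.t_fail[None, :]  # risk/exposure, (n, J)
        self.Tindex = np.searchsorted(self.t_fail, T)
        for i in range(self.n):
            if self.delta[i] == 1 and (
                self.Tindex[i] >= self.J or self.t_fail[self.Tindex[i]] != T[i]
            ):
                raise ValueError(
                    f"subject {dataset.subjects[i].id!r}: event time not among "
                    "observed failure times"
                )
        # z_ik(t_j) stacked into block coordinates: (n, J, r)
        self.Wz = np.zeros((self.n, self.J, self.r))
        bad_const = False
        for k, spec in enumerate(dataset.specs):
            lo = self.r_offsets[k]
            for c_idx in range(spec.r):
                col = lo + c_idx
                consts = np.array(
                    [
                        np.nan if s.z_const[k][c_idx] is None else s.z_const[k][c_idx]
                        for s in dataset.subjects
                    ]
                )
                is_time = [s.z_const[k][c_idx] is None for s in dataset.subjects]
                if all(is_time):
                    self.Wz[:, :, col] = self.t_fail[None, :]
                else:
                    if np.any(np.isnan(consts)):
                        bad_const = True
                        consts = np.nan_to_num(consts)
                    self.Wz[:, :, col] = consts[:, None]
        if bad_const:
            warnings.warn(
                "some subjects have undetermined constant random covariates "
                "(no measurements); their hazard contribution uses 0"
            )

    # -- draws ------------------------------------------------------------

    def draw_all(self, theta: ParameterSet, N: int, rng):
        mean, A, chol = self.cache.posterior_moments(
            theta.beta, theta.D, theta.sigma2
        )
        omega = rng.standard_normal((self.n, N // 2, self.r))
        shift = np.einsum("nij,nmj->nmi", chol, omega)
        b = np.empty((self.n, N, self.r))
        b[:, 0::2] = mean[:, None, :] + shift
        b[:, 1::2] = mean[:, None, :] - shift
        return b, mean, A

    def _wk(self, b_chunk, idx, Jc=None):
        """Association covariates w (nc, N, Jc, K) for subject indices idx.

        Computed in the dtype of ``b_chunk`` (float32 on the fast path).
        """
        if Jc is None:
            Jc = self.J
        nc, N = b_chunk.shape[0], b_chunk.shape[1]
        Wz = self.Wz.astype(b_chunk.dtype, copy=False)
        wk = np.empty((nc, N, Jc, self.K), dtype=b_chunk.dtype)
        for k in range(self.K):
            lo, hi = self.r_offsets[k], self.r_offsets[k + 1]
            wk[..., k] = np.einsum(
                "nmr,njr->nmj", b_chunk[..., lo:hi], Wz[idx, :Jc, lo:hi]
            )
        return wk

    def _chunks(self, N):
        """Subject index chunks ordered by follow-up time, with the number of
        baseline-hazard atoms each chunk actually needs."""
        n_atoms = np.searchsorted(self.t_fail, self.T, side="right")
        perm = np.argsort(n_atoms, kind="stable")
        budget = 4_000_000
        out = []
        lo = 0
        while lo < self.n:
            hi = lo + 1
            while hi < self.n:
                Jc = max(1, int(n_atoms[perm[hi]]))
                if (hi + 1 - lo) * N * Jc > budget:
                    break
                hi += 1
            idx = perm[lo:hi]
            Jc = max(1, int(n_atoms[idx].max())) if self.J else 0
            out.append((idx, Jc))
            lo = hi
        return out

    def estep(self, theta: ParameterSet, N: int, rng,
              need_ww: bool = True) -> EStepExpectations:
        b, mean, A = self.draw_all(theta, N, rng)
        base = self.V @ theta.gamma_v if self.q else np.zeros(self.n)
        lam = theta.lambda0
        Eb = np.empty((self.n, self.r))
        Ebb = np.empty((self.n, self.r, self.r))
        EexpW2 = np.zeros((self.n, self.J))
        EexpW2w = np.zeros((self.n, self.J, self.K))
        EexpW2ww = (
            np.zeros((self.n, self.J, self.K, self.K)) if need_ww else None
        )
        Ew_T = np.zeros((self.n, self.K))
        wt_all = np.empty((self.n, N))
        # heavy (n, N, J) intermediates run in float32: their contribution to
        # the expectations is far below the MC noise floor at any usable N
        clip32 = np.float32(80.0)
        gy32 = theta.gamma_y.astype(np.float32)
        for idx, Jc in self._chunks(N):
            bc = b[idx]
            wk = self._wk(bc.astype(np.float32), idx, Jc)
            W2 = np.einsum("nmjk,k->nmj", wk, gy32)
            W2 = np.where(self.mask[idx, :Jc][:, None, :], W2,
                          np.float32(-np.inf))
            expW2 = np.exp(np.minimum(W2, clip32))
            cum = (
                expW2 @ lam[:Jc].astype(np.float32)
                if self.J
                else np.zeros(bc.shape[:2], dtype=np.float32)
            )
            logw = -(
                np.exp(np.minimum(base[idx], _EXP_CLIP)).astype(np.float32)[
                    :, None
                ]
                * cum
            )
            ev = np.flatnonzero(self.delta[idx] == 1)
            if ev.size:
                jev = self.Tindex[idx][ev]
                logw[ev] += (
                    np.log(lam[jev])[:, None]
                    + base[idx][ev][:, None]
                    + wk[ev, :, jev, :] @ theta.gamma_y
                ).astype(np.float32)
            m = logw.max(axis=1)
            if np.any(~np.isfinite(m)):
                i_bad = int(idx[np.flatnonzero(~np.isfinite(m))[0]])
                raise ValueError(
                    "degenerate survival weights for subject "
                    f"{self.dataset.subjects[i_bad].id!r}"
                )
            w = np.exp(logw - m[:, None])
            wt = (w / w.sum(axis=1, keepdims=True)).astype(np.float64)
            wt_all[idx] = wt
            Eb[idx] = np.einsum("nm,nmr->nr", wt, bc)
            Ebb[idx] = np.einsum("nm,nmr,nms->nrs", wt, bc, bc)
            wexp = wt.astype(np.float32)[:, :, None] * expW2  # (nc, N, Jc)
            EexpW2[idx, :Jc] = wexp.sum(axis=1, dtype=np.float64)
            EexpW2w[idx, :Jc] = np.einsum("nmj,nmjk->njk", wexp, wk)
            if need_ww:
                EexpW2ww[idx, :Jc] = np.einsum(
                    "nmj,nmjk,nmjl->njkl", wexp, wk, wk
                )
            if ev.size:
                Ew_T[idx[ev]] = np.einsum(
                    "nm,nmk->nk", wt[ev], wk[ev, :, jev, :].astype(np.float64)
                )
        return EStepExpectations(
            Eb, Ebb, EexpW2, EexpW2w, EexpW2ww, Ew_T, b, wt_all, N
        )

    def log_weights(self, theta: ParameterSet, b: np.ndarray) -> np.ndarray:
        """log f(T_i, delta_i | b; theta) for draws b of shape (n, N, r)."""
        N = b.shape[1]
        base = self.V @ theta.gamma_v if self.q else np.zeros(self.n)
        lam = theta.lambda0
        logw = np.empty((self.n, N))
        for idx, Jc in self._chunks(N):
            wk = self._wk(b[idx], idx, Jc)
            W2 = np.einsum("nmjk,k->nmj", wk, theta.gamma_y)
            W2m = np.where(self.mask[idx, :Jc][:, None, :], W2, -np.inf)
            expW2 = np.exp(np.minimum(W2m, _EXP_CLIP))
            cum = expW2 @ lam[:Jc] if self.J else np.zeros(b[idx].shape[:2])
            lw = -np.exp(np.minimum(base[idx], _EXP_CLIP))[:, None] * cum
            ev = np.flatnonzero(self.delta[idx] == 1)
            if ev.size:
                jev = self.Tindex[idx][ev]
                lw[ev] += (
                    np.log(lam[jev])[:, None]
                    + base[idx][ev][:, None]
                    + wk[ev, :, jev, :] @ theta.gamma_y
                )
            logw[idx] = lw
        return logw

    # -- M-step pieces -----------------------------------------------------

    def update_beta_sigma_D(self, exp_: EStepExpectations):
        Var = exp_.Ebb - np.einsum("ni,nj->nij", exp_.Eb, exp_.Eb)
        beta, sigma2, Ebb, D = _em_mstep(self.cache, exp_.Eb, Var)
        return beta, sigma2, D

    def gamma_score_info(self, exp_: EStepExpectations, theta: ParameterSet,
                         method: str = "NR"):
        """Score S(gamma) and information (NR observed / GN empirical)."""
        lam = theta.lambda0
        base = np.exp(
            np.minimum(self.V @ theta.gamma_v if self.q else np.zeros(self.n),
                       _EXP_CLIP)
        )
        cum0 = exp_.EexpW2 @ lam  # (n,)
        cum1 = np.einsum("njk,j->nk", exp_.EexpW2w, lam)  # (n, K)
        obs = np.concatenate([self.V, exp_.Ew_T], axis=1)  # (n, q+K)
        expd = np.concatenate(
            [base[:, None] * cum0[:, None] * self.V, base[:, None] * cum1], axis=1
        )
        s_i = self.delta[:, None] * obs - expd  # (n, q+K)
        score = s_i.sum(axis=0)
        if method == "GN":
            info = np.einsum("ni,nj->ij", s_i, s_i) - np.outer(score, score) / self.n
        else:
            cum2 = np.einsum("njkl,j->nkl", exp_.EexpW2ww, lam)  # (n, K, K)
            I_vv = np.einsum("n,na,nb->ab", base * cum0, self.V, self.V)
            I_vy = np.einsum("n,na,nk->ak", base, self.V, cum1)
            I_yy = np.einsum("n,nkl->kl", base, cum2)
            info = np.block([[I_vv, I_vy], [I_vy.T, I_yy]])
        return score, info, s_i

    def breslow(self, exp_: EStepExpectations, theta: ParameterSet) -> np.ndarray:
        """Breslow increments d_j / sum_{risk} E[exp(v'g_v + W_2(t_j,b))].

        Uses the E-step expectations as supplied, i.e. the baseline hazard
        is paired with the gamma at which the expectations were computed.
        """
        if self.J == 0:
            return np.array([])
        base = np.exp(
            np.minimum(self.V @ theta.gamma_v if self.q else np.zeros(self.n),
                       _EXP_CLIP)
        )
        denom = base @ exp_.EexpW2  # mask already applied in the E-step
        if np.any(denom <= 0):
            raise np.linalg.LinAlgError("empty risk set at a failure time")
        return self.d / denom


# ---------------------------------------------------------------------------
# public M-step / monitoring operations
# ---------------------------------------------------------------------------


def mstep_beta_sigma_D(dataset: JointDataset, expectations: EStepExpectations,
                       theta: ParameterSet):
    """Closed-form updates for beta, sigma^2 and D given E-step expectations."""
    return _JointEngine(dataset).update_beta_sigma_D(expectations)


def mstep_baseline_hazard(dataset: JointDataset, expectations: EStepExpectations,
                          theta: ParameterSet) -> np.ndarray:
    return _JointEngine(dataset).breslow(expectations, theta)


def gamma_score_information(dataset: JointDataset, expectations: EStepExpectations,
                            theta: ParameterSet, method: str = "NR"):
    score, info, _ = _JointEngine(dataset).gamma_score_info(
        expectations, theta, method
    )
    return score, info


def gamma_onestep_update(gamma: np.ndarray, score: np.ndarray, info: np.ndarray,
                         method: str = "NR") -> np.ndarray:
    """One Newton step: gamma + kappa * info^-1 score (kappa 1 for NR, 0.5 for GN)."""
    kappa = 1.0 if method == "NR" else 0.5
    try:
        step = np.linalg.solve(info, score)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular information in gamma update; consider method='GN' or "
            "a ridge adjustment"
        ) from err
    out = np.asarray(gamma, float) + kappa * step
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite gamma update")
    return out


@dataclass
class ConvergenceState:
    """History of the stopping-rule quantities across MCEM iterations."""

    theta_history: list = field(default_factory=list)
    delta_rel: list = field(default_factory=list)
    delta_abs: list = field(default_factory=list)
    passes: int = 0
    N_history: list = field(default_factory=list)

    def update(self, theta_flat: np.ndarray, control: MCEMControl):
        """Record an iterate; returns (converged_now, delta_rel)."""
        self.theta_history.append(np.asarray(theta_flat, float).copy())
        if len(self.theta_history) < 2:
            return False, np.inf
        prev = self.theta_history[-2]
        curr = self.theta_history[-1]
        diff = np.abs(curr - prev)
        d_rel = float(np.max(diff / (np.abs(prev) + control.tol_denom)))
        d_abs = float(np.max(diff))
        self.delta_rel.append(d_rel)
        self.delta_abs.append(d_abs)
        if control.criterion == "rel":
            ok = d_rel < control.tol_rel
        elif control.criterion == "abs":
            ok = d_abs < control.tol_abs
        else:  # hybrid: near-zero components by absolute difference
            near0 = np.abs(prev) < 0.01
            rel = diff / (np.abs(prev) + control.tol_denom)
            ok = bool(
                np.all(np.where(near0, diff < control.tol_abs,
                                rel < control.tol_rel))
            )
        self.passes = self.passes + 1 if ok else 0
        return self.passes >= control.consecutive, d_rel


def convergence_check(state: ConvergenceState, control: MCEMControl):
    """Convergence status from the recorded history (last recorded iterate)."""
    if len(state.theta_history) < 2:
        return False, np.inf
    return state.passes >= control.consecutive, state.delta_rel[-1]


def _cv(window) -> float:
    w = np.asarray(window, float)
    m = w.mean()
    if m == 0:
        return 0.0
    return float(np.std(w, ddof=1) / m)


def adapt_mc_size(state: ConvergenceState, N: int, control: MCEMControl,
                  in_burnin: bool = False) -> int:
    """Grow N when the coefficient of variation of Delta_rel increases.

    cv is computed over the last three Delta_rel values and compared with
    the previous (overlapping) window; inactive during burn-in.
    """
    if in_burnin or len(state.delta_rel) < 4:
        return N
    cv_now = _cv(state.delta_rel[-3:])
    cv_prev = _cv(state.delta_rel[-4:-1])
    if cv_now > cv_prev:
        N = N + N // control.delta
        if N % 2:
            N += 1
        if control.max_N is not None:
            N = min(N, control.max_N + control.max_N % 2)
    return N


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------


def _initial_theta(dataset: JointDataset, engine: _JointEngine,
                   lmm_tol: float = 1e-6) -> ParameterSet:
    """Initial values: separate LMMs -> multivariate LMM EM -> two-stage Cox."""
    separate = [
        fit_univariate_lmm(dataset, k, tol=lmm_tol) for k in range(dataset.K)
    ]
    if dataset.K > 1:
        beta, D, sigma2, _ = mvlmm_em(dataset, init=separate, tol=lmm_tol)
    else:
        beta, D, sigma2 = (
            separate[0].beta_k, separate[0].D_kk, np.array([separate[0].sigma2_k])
        )
    gamma_v0, gamma_y0 = two_stage_initial_values(dataset, separate)
    theta = ParameterSet(beta, D, sigma2, gamma_v0, gamma_y0,
                         engine.t_fail, np.ones(engine.J))
    theta.lambda0 = _initial_lambda0(dataset, engine, theta)
    return theta


def _initial_lambda0(dataset: JointDataset, engine: _JointEngine,
                     theta: ParameterSet) -> np.ndarray:
    """Breslow increments with W_2 plugged in at the posterior-mean BLUPs."""
    if engine.J == 0:
        return np.array([])
    mean, _, _ = engine.cache.posterior_moments(theta.beta, theta.D, theta.sigma2)
    W2 = np.einsum("njr,nr->nj", engine.Wz * _gamma_y_expand(engine, theta),
                   mean)
    base = engine.V @ theta.gamma_v if engine.q else np.zeros(engine.n)
    eta = np.where(engine.mask, base[:, None] + W2, -np.inf)
    denom = np.exp(np.minimum(eta, _EXP_CLIP)).sum(axis=0)
    return engine.d / denom


def _gamma_y_expand(engine: _JointEngine, theta: ParameterSet) -> np.ndarray:
    g = np.empty(engine.r)
    for k in range(engine.K):
        g[engine.r_offsets[k] : engine.r_offsets[k + 1]] = theta.gamma_y[k]
    return g


def mcem_fit(dataset: JointDataset, control: MCEMControl | None = None,
             init: ParameterSet | None = None) -> FitResult:
    """Fit the joint model by Monte Carlo EM.

    Initialises from separate linear mixed fits, a multivariate LMM EM and a
    quasi-two-stage Cox model unless ``init`` is given.  Fully reproducible
    given ``control.seed``.
    """
    control = (control or MCEMControl()).resolve(dataset.K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        validate_dataset(dataset)
    engine = _JointEngine(dataset)
    rng = np.random.default_rng(control.seed)
    if init is None:
        theta = _initial_theta(dataset, engine)
    else:
        theta = init.copy()
        if theta.lambda0.size != engine.J or not np.array_equal(
            theta.lambda0_times, engine.t_fail
        ):
            theta.lambda0_times = engine.t_fail
            theta.lambda0 = _initial_lambda0(dataset, engine, theta)
    labels = theta.labels(dataset)
    state = ConvergenceState()
    state.update(theta.flat(), control)
    N = control.N0
    trace_rows = []
    messages: list[str] = []
    converged = False
    n_iter = 0
    for m in range(1, control.max_iter + 1):
        n_iter = m
        exp_ = engine.estep(
            theta, N, rng, need_ww=(control.gamma_update == "NR")
        )
        beta, sigma2, D = engine.update_beta_sigma_D(exp_)
        theta_new = ParameterSet(
            beta, D, sigma2, theta.gamma_v.copy(), theta.gamma_y.copy(),
            engine.t_fail, theta.lambda0.copy(),
        )
        score, info, _ = engine.gamma_score_info(exp_, theta, control.gamma_update)
        gamma = gamma_onestep_update(
            np.concatenate([theta.gamma_v, theta.gamma_y]), score, info,
            control.gamma_update,
        )
        theta_new.gamma_v = gamma[: engine.q]
        theta_new.gamma_y = gamma[engine.q :]
        theta_new.lambda0 = engine.breslow(exp_, theta)
        theta = theta_new
        conv_now, d_rel = state.update(theta.flat(), control)
        trace_rows.append(
            [m, N, d_rel, state.delta_abs[-1]] + list(theta.flat())
        )
        state.N_history.append(N)
        if m > control.burnin and conv_now:
            converged = True
            break
        N = adapt_mc_size(state, N, control, in_burnin=(m <= control.burnin))
    if not converged:
        messages.append(
            f"MCEM did not converge within max_iter={control.max_iter}"
        )
        warnings.warn(messages[-1])
    trace = pd.DataFrame(
        trace_rows, columns=["iteration", "N", "delta_rel", "delta_abs"] + labels
    )
    from . import inference

    ll_N = min(control.se_N_factor * N, 20_000)
    if ll_N % 2:
        ll_N += 1
    loglik = inference.observed_loglik(theta, dataset, ll_N, rng)
    se = vcov = None
    if control.se_method == "empirical":
        try:
            se_res = inference.empirical_information_se(
                theta, dataset, ll_N, rng
            )
            se, vcov = se_res.se, se_res.vcov
        except np.linalg.LinAlgError as err:
            messages.append(f"empirical information SEs unavailable: {err}")
            warnings.warn(messages[-1])
    result = FitResult(
        theta_hat=theta, se=se, vcov=vcov, loglik=loglik, trace=trace,
        converged=converged, n_iter=n_iter, final_N=N, labels=labels,
        n_subjects=dataset.n, messages=messages,
    )
    if control.se_method == "bootstrap":
        se_res = inference.bootstrap_se(result, dataset, B=100, control=control,
                                        rng=rng)
        result.se = se_res.se
    return result


class MultivariateJointModel(BaseEstimator):
    """Joint model for K longitudinal outcomes and a right-censored event time.

    A shared zero-mean Gaussian random-effects process links a multivariate
    linear mixed sub-model with a semiparametric proportional hazards
    sub-model; estimation is by Monte Carlo EM with antithetic sampling and
    a dynamically grown Monte Carlo size.

    Parameters mirror :class:`~mvjoint.data.MCEMControl`; fitted attributes
    are ``params_`` (a :class:`ParameterSet`), ``se_``, ``vcov_``,
    ``loglik_``, ``trace_``, ``converged_``, ``n_iter_`` and ``final_N_``.
    """

    def __init__(self, tol_rel=0.005, tol_denom=0.001, tol_abs=0.005,
                 criterion="hybrid", N0=None, burnin=None, delta=3, consecutive=3,
                 max_N=None, max_iter=600, gamma_update="NR", seed=None,
                 se_method="empirical", se_N_factor=4):
        self.tol_rel = tol_rel
        self.tol_denom = tol_denom
        self.tol_abs = tol_abs
        self.criterion = criterion
        self.N0 = N0
        self.burnin = burnin
        self.delta = delta
        self.consecutive = consecutive
        self.max_N = max_N
        self.max_iter = max_iter
        self.gamma_update = gamma_update
        self.seed = seed
        self.se_method = se_method
        self.se_N_factor = se_N_factor

    def control(self) -> MCEMControl:
        return MCEMControl(
            tol_rel=self.tol_rel, tol_denom=self.tol_denom, tol_abs=self.tol_abs,
            criterion=self.criterion, N0=self.N0, burnin=self.burnin,
            delta=self.delta, consecutive=self.consecutive,
            max_N=self.max_N, max_iter=self.max_iter,
            gamma_update=self.gamma_update,
            seed=self.seed, se_method=self.se_method,
            se_N_factor=self.se_N_factor,
        )

    def fit(self, dataset: JointDataset, y=None, init: ParameterSet | None = None):
        res = mcem_fit(dataset, self.control(), init=init)
        self.result_ = res
        self.params_ = res.theta_hat
        self.se_ = res.se
        self.vcov_ = res.vcov
        self.loglik_ = res.loglik
        self.trace_ = res.trace
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.final_N_ = res.final_N
        self.labels_ = res.labels
        return self

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return self.result_.summary(level)
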