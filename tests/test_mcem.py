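import numpy as np
import pytest

import mvjoint as mj
from mvjoint.data import MCEMControl, ParameterSet
from mvjoint.lmm import posterior_re_moments, REPosteriorMoments
from mvjoint.mcem import (
    ConvergenceState,
    EStepExpectations,
    _JointEngine,
    adapt_mc_size,
    conditional_expectation,
    draw_antithetic,
    gamma_onestep_update,
    mcem_fit,
    survival_log_weight,
    MCDraws,
)

from conftest import grid_posterior


class TestAntitheticDraws:
    def test_pair_means_exact(self, tiny_toy):
        ds, theta = tiny_toy
        mom = posterior_re_moments(ds.subjects[0], theta)
        dr = draw_antithetic(mom, 1000, np.random.default_rng(0))
        pairs = dr.draws.reshape(500, 2, 2).mean(axis=1)
        np.testing.assert_allclose(pairs, np.tile(mom.mean, (500, 1)),
                                   atol=1e-12)

    def test_n2_single_pair(self, tiny_toy):
        ds, theta = tiny_toy
        mom = posterior_re_moments(ds.subjects[0], theta)
        dr = draw_antithetic(mom, 2, np.random.default_rng(1))
        assert dr.draws.shape == (2, 2)
        np.testing.assert_allclose(dr.draws.mean(axis=0), mom.mean, atol=1e-12)

    def test_odd_n_rejected(self, tiny_toy):
        ds, theta = tiny_toy
        mom = posterior_re_moments(ds.subjects[0], theta)
        with pytest.raises(ValueError, match="even"):
            draw_antithetic(mom, 3, np.random.default_rng(0))

    def test_sample_cov_converges_to_posterior_cov(self):
        cov = np.array([[0.4, 0.1], [0.1, 0.2]])
        mom = REPosteriorMoments(np.array([1.0, -1.0]), cov,
                                 np.linalg.cholesky(cov))
        dr = draw_antithetic(mom, 100_000, np.random.default_rng(2))
        S = np.cov(dr.draws.T)
        assert np.linalg.norm(S - cov) / np.linalg.norm(cov) < 0.05


class TestSurvivalLogWeight:
    def test_censored_before_first_failure_is_zero(self, tiny_toy):
        ds, theta = tiny_toy
        s = ds.subjects[1]
        th = theta.copy()
        th.lambda0_times = np.array([5.0])
        th.lambda0 = np.array([0.4])
        assert survival_log_weight(np.zeros(2), s, th) == 0.0

    def test_plugin_value(self, tiny_toy):
        # gamma = 0, event at the only atom with lambda01 = 0.2
        ds, theta = tiny_toy
        th = theta.copy()
        th.gamma_v = np.array([0.0])
        th.gamma_y = np.array([0.0])
        th.lambda0 = np.array([0.2])
        lw = survival_log_weight(np.zeros(2), ds.subjects[0], th)
        assert lw == pytest.approx(np.log(0.2) - 0.2)

    def test_event_off_atom_rejected(self, tiny_toy):
        ds, theta = tiny_toy
        th = theta.copy()
        th.lambda0_times = np.array([0.7])
        with pytest.raises(ValueError, match="atom"):
            survival_log_weight(np.zeros(2), ds.subjects[0], th)

    def test_step_sum_refines_to_continuous_hazard(self, tiny_toy):
        """As the baseline steps refine a continuous log-linear hazard, the
        step cumulative hazard converges to the closed-form integral."""
        ds, theta = tiny_toy
        s = ds.subjects[1]  # censored at 2.5
        a, c = 0.25, -0.6
        b = np.array([0.3, -0.2])
        th = theta.copy()
        errs = []
        for m in (40, 160, 640):
            knots = np.linspace(0, s.time, m + 1)
            mids = knots[1:]
            # increments integrate exp(a + c t) over each segment
            lam = (np.exp(a + c * knots[1:]) - np.exp(a + c * knots[:-1])) / c
            th.lambda0_times = mids
            th.lambda0 = lam
            lw = survival_log_weight(b, s, th)
            # exact: -int_0^T exp(a + c u) exp(g*(b0 + b1 u)) du
            g = th.gamma_y[0]
            rate = c + g * b[1]
            exact = -(
                np.exp(a + g * b[0]) * (np.exp(rate * s.time) - 1.0) / rate
            )
            errs.append(abs(lw - exact))
        assert errs[2] < errs[0]
        assert errs[2] < 2e-3


class TestConditionalExpectation:
    def test_constant_function(self):
        dr = MCDraws(np.random.default_rng(0).standard_normal((10, 2)),
                     np.array([-5.0, 0.0] * 5))
        np.testing.assert_allclose(
            conditional_expectation(lambda b: 3.5, dr), 3.5
        )

    def test_constant_weights_give_posterior_mean(self, tiny_toy):
        ds, theta = tiny_toy
        mom = posterior_re_moments(ds.subjects[0], theta)
        dr = draw_antithetic(mom, 400, np.random.default_rng(3))
        dr.log_weights = np.full(400, -2.0)
        np.testing.assert_allclose(
            conditional_expectation(lambda b: b, dr), mom.mean, atol=1e-12
        )

    def test_degenerate_weights_error(self):
        dr = MCDraws(np.zeros((4, 1)), np.full(4, -np.inf))
        with pytest.raises(ValueError, match="degenerate"):
            dr.weights()

    def test_matches_grid_quadrature(self, tiny_toy):
        """Survival-reweighted posterior mean agrees with dense-grid
        quadrature to 3 significant figures."""
        ds, theta = tiny_toy
        s = ds.subjects[0]
        pts, w = grid_posterior(s, theta)
        target = w @ pts
        eng = _JointEngine(ds)
        exp_ = eng.estep(theta, 100_000, np.random.default_rng(4))
        np.testing.assert_allclose(exp_.Eb[0], target, rtol=2e-3, atol=2e-3)


class TestMStep:
    def test_breslow_hand_calculation(self):
        """gamma = 0: increments are the Nelson-Aalen 1/3 and 1/2."""
        rng = np.random.default_rng(0)
        ds = mj.simulate_joint(mj.SimScenario(n=3, censor_rate=0.0), rng)
        for s, (T, d) in zip(ds.subjects, [(1.0, 1), (2.0, 1), (3.0, 0)]):
            s.time, s.event = T, d
        eng = _JointEngine(ds)
        exp_ = _unit_expectations(eng)
        th = _zero_gamma_theta(eng)
        lam = eng.breslow(exp_, th)
        np.testing.assert_allclose(lam, [1 / 3, 1 / 2])

    def test_breslow_homogeneity(self):
        rng = np.random.default_rng(1)
        ds = mj.simulate_joint(mj.SimScenario(n=20), rng)
        eng = _JointEngine(ds)
        exp_ = _unit_expectations(eng)
        th = _zero_gamma_theta(eng)
        lam1 = eng.breslow(exp_, th)
        exp_.EexpW2 = 2.0 * exp_.EexpW2
        lam2 = eng.breslow(exp_, th)
        np.testing.assert_allclose(lam2, lam1 / 2.0)

    def test_breslow_self_consistency(self):
        """sum_j lambda_0j * (risk-set denominator) equals the event count."""
        rng = np.random.default_rng(5)
        ds = mj.simulate_joint(mj.SimScenario(n=40), rng)
        eng = _JointEngine(ds)
        theta = mj.SimScenario().true_parameters()
        theta.lambda0_times = eng.t_fail
        theta.lambda0 = np.full(eng.J, 0.1)
        exp_ = eng.estep(theta, 200, np.random.default_rng(0))
        lam = eng.breslow(exp_, theta)
        base = np.exp(eng.V @ theta.gamma_v)
        denom = base @ exp_.EexpW2
        assert np.sum(lam * denom) == pytest.approx(ds.n_events)

    def test_D_trace_identity(self, small_dataset):
        eng = _JointEngine(small_dataset)
        theta = mj.SimScenario().true_parameters()
        theta.lambda0_times = eng.t_fail
        theta.lambda0 = np.full(eng.J, 0.05)
        exp_ = eng.estep(theta, 100, np.random.default_rng(1))
        _, _, D = eng.update_beta_sigma_D(exp_)
        Var = exp_.Ebb - np.einsum("ni,nj->nij", exp_.Eb, exp_.Eb)
        expected = np.mean(
            np.trace(Var, axis1=1, axis2=2)
            + np.einsum("ni,ni->n", exp_.Eb, exp_.Eb)
        )
        assert np.trace(D) == pytest.approx(expected, rel=1e-8)

    def test_beta_update_matches_lmm_when_decoupled(self, small_dataset):
        """With gamma_y = 0 the survival weights are constant and the
        antithetic mean is the exact posterior mean, so the MCEM beta update
        equals the deterministic EM beta update exactly."""
        from mvjoint.lmm import DesignCache, _em_mstep

        eng = _JointEngine(small_dataset)
        theta = mj.SimScenario().true_parameters()
        theta.gamma_y = np.zeros(2)
        theta.gamma_v = np.zeros(2)
        theta.lambda0_times = eng.t_fail
        theta.lambda0 = np.full(eng.J, 0.05)
        exp_ = eng.estep(theta, 50, np.random.default_rng(2))
        beta_mc, _, _ = eng.update_beta_sigma_D(exp_)
        cache = DesignCache(small_dataset)
        mean, A, _ = cache.posterior_moments(theta.beta, theta.D, theta.sigma2)
        beta_em, _, _, _ = _em_mstep(cache, mean, A)
        # the E-step's float32 fast path leaves ~1e-8 rounding in the
        # (otherwise exact) constant weights
        np.testing.assert_allclose(beta_mc, beta_em, atol=1e-6)


def _unit_expectations(eng):
    """EStepExpectations with E[exp(W2)] = 1 on the risk set (gamma_y = 0)."""
    return EStepExpectations(
        Eb=np.zeros((eng.n, eng.r)),
        Ebb=np.tile(np.eye(eng.r), (eng.n, 1, 1)),
        EexpW2=eng.mask.astype(float),
        EexpW2w=np.zeros((eng.n, eng.J, eng.K)),
        EexpW2ww=np.zeros((eng.n, eng.J, eng.K, eng.K)),
        Ew_T=np.zeros((eng.n, eng.K)),
        draws=np.zeros((eng.n, 2, eng.r)),
        weights=np.full((eng.n, 2), 0.5),
        N=2,
    )


def _zero_gamma_theta(eng):
    return ParameterSet(
        beta=np.zeros(sum(eng.cache.p_blocks)),
        D=np.eye(eng.r),
        sigma2=np.ones(eng.K),
        gamma_v=np.zeros(eng.q),
        gamma_y=np.zeros(eng.K),
        lambda0_times=eng.t_fail,
        lambda0=np.full(eng.J, 0.1),
    )


class TestGammaUpdate:
    def test_score_and_nr_info_match_bruteforce_fd(self, tiny_toy):
        """NR information equals central finite differences of the negative
        score on frozen draws and weights (1e-3 relative)."""
        ds, theta = tiny_toy
        eng = _JointEngine(ds)
        exp_ = eng.estep(theta, 2000, np.random.default_rng(3))
        b, wt = exp_.draws, exp_.weights
        wk = np.einsum("nmr,njr->nmj", b, eng.Wz)[..., None]
        V, lam, mask = eng.V, theta.lambda0, eng.mask

        def score_bf(gam):
            gv, gy = gam[:1], gam[1:]
            eta = (V @ gv)[:, None, None] + wk[..., 0] * gy[0]
            ex = np.exp(eta) * mask[:, None, :]
            out = np.zeros(2)
            for i in range(eng.n):
                obs = np.zeros(2)
                if eng.delta[i] == 1:
                    j = eng.Tindex[i]
                    obs = np.array([V[i, 0], wt[i] @ wk[i, :, j, 0]])
                cum = np.array(
                    [wt[i] @ (ex[i] @ lam) * V[i, 0],
                     wt[i] @ ((ex[i] * wk[i, :, :, 0]) @ lam)]
                )
                out += eng.delta[i] * obs - cum
            return out

        g0 = np.concatenate([theta.gamma_v, theta.gamma_y])
        score, info, _ = eng.gamma_score_info(exp_, theta, "NR")
        # float32 E-step intermediates bound the agreement, not the algebra
        np.testing.assert_allclose(score, score_bf(g0), rtol=1e-5)
        eps = 1e-5
        fd = np.zeros((2, 2))
        for a in range(2):
            e = np.zeros(2)
            e[a] = eps
            fd[:, a] = -(score_bf(g0 + e) - score_bf(g0 - e)) / (2 * eps)
        assert np.abs(info - fd).max() / np.abs(fd).max() < 1e-3

    def test_gn_information_zero_for_identical_scores(self):
        # I_e = sum s s' - (1/n)(ns)(ns)' = 0 when all subjects share s
        s = np.array([0.5, -1.0])
        n = 7
        S = n * s
        I_e = n * np.outer(s, s) - np.outer(S, S) / n
        np.testing.assert_allclose(I_e, 0.0, atol=1e-12)

    def test_onestep_arithmetic(self):
        # 1-D: gamma=0, S=2, I=4 -> NR 0.5, GN 0.25
        assert gamma_onestep_update(
            np.array([0.0]), np.array([2.0]), np.array([[4.0]]), "NR"
        )[0] == pytest.approx(0.5)
        assert gamma_onestep_update(
            np.array([0.0]), np.array([2.0]), np.array([[4.0]]), "GN"
        )[0] == pytest.approx(0.25)

    def test_zero_score_leaves_gamma(self):
        g = np.array([1.0, -2.0])
        out = gamma_onestep_update(g, np.zeros(2), np.eye(2), "NR")
        np.testing.assert_array_equal(out, g)


class TestMonitoring:
    def _control(self, criterion="rel"):
        return MCEMControl(tol_rel=0.005, tol_denom=0.001, tol_abs=0.005,
                           criterion=criterion, consecutive=3, N0=100)

    def test_identical_iterates_pass(self):
        ctl = self._control()
        st = ConvergenceState()
        st.update(np.array([1.0, 2.0]), ctl)
        conv, d = st.update(np.array([1.0, 2.0]), ctl)
        assert d == 0.0 and st.passes == 1 and not conv

    def test_counter_resets_on_failure(self):
        ctl = self._control(criterion="abs")
        st = ConvergenceState()
        st.update(np.array([1.0]), ctl)
        st.update(np.array([1.001]), ctl)   # pass 1
        st.update(np.array([1.002]), ctl)   # pass 2
        conv, _ = st.update(np.array([1.5]), ctl)  # fail
        assert st.passes == 0 and not conv
        st.update(np.array([1.501]), ctl)
        st.update(np.array([1.502]), ctl)
        conv, _ = st.update(np.array([1.503]), ctl)
        assert conv  # three fresh consecutive passes

    def test_relative_difference_arithmetic(self):
        ctl = self._control()
        st = ConvergenceState()
        st.update(np.array([1.0, 0.001]), ctl)
        conv, d = st.update(np.array([1.004, 0.0011]), ctl)
        assert d == pytest.approx(0.05)
        assert not conv and st.passes == 0

    def test_adapt_constant_history_keeps_N(self):
        ctl = self._control()
        st = ConvergenceState()
        st.delta_rel = [0.1, 0.1, 0.1, 0.1]
        assert adapt_mc_size(st, 100, ctl) == 100

    def test_adapt_growth_and_even_rounding(self):
        ctl = self._control()
        st = ConvergenceState()
        st.delta_rel = [0.1, 0.1, 0.1, 0.5]  # cv increased
        assert adapt_mc_size(st, 100, ctl) == 134

    def test_adapt_inactive_during_burnin(self):
        ctl = self._control()
        st = ConvergenceState()
        st.delta_rel = [0.1, 0.1, 0.1, 0.5]
        assert adapt_mc_size(st, 100, ctl, in_burnin=True) == 100

    def test_defaults_scale_with_K(self):
        ctl = MCEMControl().resolve(2)
        assert ctl.N0 == 200 and ctl.burnin == 200


class TestAntitheticVarianceReduction:
    def test_linear_functional_variance_not_worse_than_iid(self, tiny_toy):
        """MC standard error of E[b0] with antithetic pairs is no larger than
        with iid draws at equal N (200 repeated E-steps on one subject)."""
        ds, theta = tiny_toy
        s = ds.subjects[0]
        mom = posterior_re_moments(s, theta)
        rng = np.random.default_rng(10)
        N = 64
        est_anti, est_iid = [], []
        for _ in range(200):
            dr = draw_antithetic(mom, N, rng)
            lw = np.array([survival_log_weight(b, s, theta) for b in dr.draws])
            dr.log_weights = lw
            est_anti.append(conditional_expectation(lambda b: b[0], dr))
            draws = mom.mean + rng.standard_normal((N, 2)) @ mom.chol.T
            lw = np.array([survival_log_weight(b, s, theta) for b in draws])
            dr2 = MCDraws(draws, lw)
            est_iid.append(conditional_expectation(lambda b: b[0], dr2))
        assert np.std(est_anti) <= np.std(est_iid)


class TestExactEStepEM:
    def test_loglik_monotone_with_quadrature_estep(self, tiny_toy):
        """EM with grid-quadrature expectations (the exact-E-step limit) has
        a non-decreasing observed-data log-likelihood."""
        from scipy.stats import multivariate_normal
        from mvjoint.lmm import DesignCache, _em_mstep

        ds, theta0 = tiny_toy
        eng = _JointEngine(ds)
        cache = DesignCache(ds)
        theta = theta0.copy()

        def grid_moments(th):
            out = []
            for s in ds.subjects:
                pts, w = grid_posterior(s, th, half_width=5.0, m=101)
                out.append((pts, w))
            return out

        def observed_ll(th):
            ll = cache.marginal_loglik(th.beta, th.D, th.sigma2)
            for s in ds.subjects:
                mom = posterior_re_moments(s, th)
                sd = np.sqrt(np.diag(mom.cov))
                g = [np.linspace(mom.mean[d] - 5 * sd[d],
                                 mom.mean[d] + 5 * sd[d], 101)
                     for d in range(2)]
                B0, B1 = np.meshgrid(*g, indexing="ij")
                pts = np.column_stack([B0.ravel(), B1.ravel()])
                dens = multivariate_normal.pdf(pts, mom.mean, mom.cov)
                cell = (g[0][1] - g[0][0]) * (g[1][1] - g[1][0])
                sw = np.exp([survival_log_weight(b, s, th) for b in pts])
                ll += np.log(np.sum(dens * sw) * cell)
            return ll

        lls = [observed_ll(theta)]
        for _ in range(5):
            gm = grid_moments(theta)
            Eb = np.array([w @ p for p, w in gm])
            Ebb = np.array(
                [np.einsum("m,mi,mj->ij", w, p, p) for p, w in gm]
            )
            Var = Ebb - np.einsum("ni,nj->nij", Eb, Eb)
            beta, sigma2, _, D = _em_mstep(cache, Eb, Var)
            # full gamma/lambda0 maximisation on the fixed expectations
            gamma = np.concatenate([theta.gamma_v, theta.gamma_y])
            for _inner in range(50):
                lam, score, info = _surv_mstep(eng, ds, gm, gamma)
                step = np.linalg.solve(info, score)
                gamma = gamma + step
                if np.abs(step).max() < 1e-10:
                    break
            lam, _, _ = _surv_mstep(eng, ds, gm, gamma)
            theta = ParameterSet(beta, D, sigma2, gamma[:1], gamma[1:],
                                 eng.t_fail, lam)
            lls.append(observed_ll(theta))
        assert np.all(np.diff(lls) >= -1e-8)


def _surv_mstep(eng, ds, grid_moments, gamma):
    """Profile Breslow hazard plus gamma score/info on grid expectations."""
    gv, gy = gamma[:1], gamma[1:]
    n = eng.n
    Eexp = np.zeros((n, eng.J))
    Eexpw = np.zeros((n, eng.J))
    Eexpww = np.zeros((n, eng.J))
    Ew_T = np.zeros(n)
    for i, (s, (pts, w)) in enumerate(zip(ds.subjects, grid_moments)):
        base = float(s.v @ gv)
        for j, tj in enumerate(eng.t_fail):
            if tj > s.time:
                continue
            wij = pts @ s.z_at(0, tj)
            e = np.exp(base + gy[0] * wij)
            Eexp[i, j] = w @ e
            Eexpw[i, j] = w @ (e * wij)
            Eexpww[i, j] = w @ (e * wij**2)
        if s.event == 1:
            j = eng.Tindex[i]
            Ew_T[i] = w @ (pts @ s.z_at(0, eng.t_fail[j]))
    lam = eng.d / Eexp.sum(axis=0)
    score = np.zeros(2)
    info = np.zeros((2, 2))
    for i, s in enumerate(ds.subjects):
        obs = np.array([s.v[0], Ew_T[i]]) * eng.delta[i]
        cum = np.array([lam @ Eexp[i] * s.v[0], lam @ Eexpw[i]])
        score += obs - cum
        info += np.array(
            [[lam @ Eexp[i] * s.v[0] ** 2, lam @ Eexpw[i] * s.v[0]],
             [lam @ Eexpw[i] * s.v[0], lam @ Eexpww[i]]]
        )
    return lam, score, info


class TestFullFit:
    def test_seed_reproducibility(self, small_dataset, fast_control):
        import dataclasses

        f1 = mcem_fit(small_dataset, fast_control)
        f2 = mcem_fit(small_dataset, fast_control)
        assert f1.trace.equals(f2.trace)
        np.testing.assert_array_equal(
            f1.theta_hat.flat(), f2.theta_hat.flat()
        )
        assert f1.final_N == f2.final_N

    def test_decoupled_k1_matches_univariate_lmm(self):
        """K = 1 with gamma frozen at zero: the MCEM longitudinal estimates
        settle at the linear-mixed-model ML estimates up to MC noise."""
        from test_lmm import _random_intercept_dataset
        from mvjoint.lmm import fit_univariate_lmm

        rng = np.random.default_rng(17)
        ds = _random_intercept_dataset(rng, n=120, visits=4)
        for i, s in enumerate(ds.subjects):
            s.time = float(rng.exponential(6.0))
            s.event = int(rng.random() < 0.5)
        comp = fit_univariate_lmm(ds, 0, tol=1e-8)
        eng = _JointEngine(ds)
        theta = ParameterSet(
            np.array([0.5]), np.array([[0.5]]), np.array([0.5]),
            np.zeros(0), np.zeros(1), eng.t_fail, np.full(eng.J, 0.05),
        )
        rng2 = np.random.default_rng(0)
        for _ in range(40):
            exp_ = eng.estep(theta, 100, rng2)
            beta, sigma2, D = eng.update_beta_sigma_D(exp_)
            lam = eng.breslow(exp_, theta)
            theta = ParameterSet(beta, D, sigma2, np.zeros(0), np.zeros(1),
                                 eng.t_fail, lam)
        assert theta.beta[0] == pytest.approx(comp.beta_k[0], abs=1e-3)
        assert theta.sigma2[0] == pytest.approx(comp.sigma2_k, abs=0.05)
        assert theta.D[0, 0] == pytest.approx(comp.D_kk[0, 0], abs=0.05)

    def test_fit_sanity_and_spd_iterates(self, medium_dataset, fast_control):
        fit = mcem_fit(medium_dataset, fast_control)
        assert fit.n_iter == len(fit.trace)
        # variance parameters positive at every recorded iterate
        for col in ("sigma2_1", "sigma2_2", "D_11", "D_22", "D_33", "D_44"):
            assert (fit.trace[col] > 0).all()
        th = fit.theta_hat
        assert np.linalg.eigvalsh(th.D)[0] > 0
        # Breslow self-consistency at the fitted parameters (fresh E-step)
        eng = _JointEngine(medium_dataset)
        exp_ = eng.estep(th, 400, np.random.default_rng(99))
        base = np.exp(eng.V @ th.gamma_v)
        total = np.sum(th.lambda0 * (base @ exp_.EexpW2))
        assert total == pytest.approx(medium_dataset.n_events, rel=0.1)
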