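import numpy as np
import pytest

import mvjoint as mj
from mvjoint.data import JointDataset, OutcomeSpec, ParameterSet, SubjectData


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated two-outcome dataset, 60 subjects (fast fixture)."""
    rng = np.random.default_rng(42)
    return mj.simulate_joint(mj.SimScenario(n=60), rng)


@pytest.fixture(scope="session")
def medium_dataset():
    """Simulated two-outcome dataset, 120 subjects."""
    rng = np.random.default_rng(7)
    return mj.simulate_joint(mj.SimScenario(n=120), rng)


def make_tiny_toy():
    """Two-subject, single-outcome dataset with random intercept + slope
    (r = 2), one event and one censored subject, plus a parameter set with
    a one-atom baseline hazard.  Small enough for dense-grid quadrature."""
    spec = OutcomeSpec("y", ["intercept", "time"], ["intercept", "time"], "time")
    t_obs = np.array([0.0, 1.0, 2.0])
    Z = np.column_stack([np.ones(3), t_obs])
    s1 = SubjectData(
        1, [t_obs], [np.array([0.5, 1.8, 2.2])], [Z.copy()], [Z.copy()],
        1.5, 1, np.array([1.0]), [[1.0, None]],
    )
    s2 = SubjectData(
        2, [t_obs], [np.array([0.1, 0.5, 0.4])], [Z.copy()], [Z.copy()],
        2.5, 0, np.array([0.0]), [[1.0, None]],
    )
    ds = JointDataset([s1, s2], [spec], ["x"], True)
    theta = ParameterSet(
        beta=np.array([0.2, 0.8]),
        D=np.array([[0.3, 0.05], [0.05, 0.1]]),
        sigma2=np.array([0.2]),
        gamma_v=np.array([0.4]),
        gamma_y=np.array([0.7]),
        lambda0_times=np.array([1.5]),
        lambda0=np.array([0.3]),
    )
    return ds, theta


@pytest.fixture(scope="session")
def tiny_toy():
    return make_tiny_toy()


def grid_posterior(subject, theta, half_width=4.0, m=121):
    """Dense-grid joint posterior f(b | y, T, delta) for an r=2 subject.

    Returns (points, normalised weights); the grid is centred on the
    longitudinal-only posterior and spans ``half_width`` of its sd.
    """
    from scipy.stats import multivariate_normal

    from mvjoint.lmm import posterior_re_moments
    from mvjoint.mcem import survival_log_weight

    mom = posterior_re_moments(subject, theta)
    sd = np.sqrt(np.diag(mom.cov))
    axes = [
        np.linspace(mom.mean[d] - half_width * sd[d],
                    mom.mean[d] + half_width * sd[d], m)
        for d in range(2)
    ]
    B0, B1 = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([B0.ravel(), B1.ravel()])
    logpost = multivariate_normal.logpdf(pts, mom.mean, mom.cov)
    logsw = np.array([survival_log_weight(b, subject, theta) for b in pts])
    logw = logpost + logsw
    w = np.exp(logw - logw.max())
    return pts, w / w.sum()


@pytest.fixture(scope="session")
def small_fit(small_dataset, fast_control):
    """One shared MCEM fit of the 60-subject dataset."""
    from mvjoint.mcem import mcem_fit

    return mcem_fit(small_dataset, fast_control)


@pytest.fixture(scope="session")
def fast_control():
    """Loose MCEM settings for unit tests on small datasets."""
    return mj.MCEMControl(
        N0=50, burnin=15, tol_rel=0.02, tol_abs=0.02, max_iter=120, seed=123,
        se_method="none",
    )
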