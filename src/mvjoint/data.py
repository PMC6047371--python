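"""Domain types and long-format ingestion for multivariate joint models.

A joint dataset couples, for each subject, ``K`` continuous longitudinal
outcome series with one right-censored event-time record.  Longitudinal
tables are long format (one row per measurement); the survival table has one
row per subject.  All design matrices are assembled outcome-major: the
stacked response for subject *i* is ``y_i = (y_i1', ..., y_iK')'`` and the
fixed/random design matrices are direct sums over outcomes, so that the
stacked coefficient vectors ``beta = (beta_1', ..., beta_K')'`` and random
effects ``b_i = (b_i1', ..., b_iK')'`` follow the same convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

__all__ = [
    "OutcomeSpec",
    "SubjectData",
    "JointDataset",
    "ParameterSet",
    "MCEMControl",
    "FitResult",
    "load_joint_dataset",
    "assemble_designs",
    "validate_dataset",
    "vech",
    "unvech",
    "vech_labels",
]


def vech(M: np.ndarray) -> np.ndarray:
    """Column-major lower-triangle half-vectorisation of a symmetric matrix."""
    M = np.asarray(M)
    r = M.shape[0]
    return np.concatenate([M[j:, j] for j in range(r)])


def unvech(v: np.ndarray, r: int) -> np.ndarray:
    """Inverse of :func:`vech` (returns the full symmetric matrix)."""
    M = np.zeros((r, r))
    pos = 0
    for j in range(r):
        M[j:, j] = v[pos : pos + r - j]
        pos += r - j
    return M + np.tril(M, -1).T


def vech_labels(r: int, prefix: str = "D") -> list[str]:
    return [f"{prefix}_{i + 1}{j + 1}" for j in range(r) for i in range(j, r)]


@dataclass
class OutcomeSpec:
    """Column layout of one longitudinal outcome in a long-format table.

    ``fixed_covariates`` name the columns of the fixed-effects design
    (length ``p_k``); ``random_covariates`` those of the random-effects
    design (length ``r_k``).  Intercepts are explicit constant-1 columns
    supplied by the caller.  Because the hazard evaluates the random-effects
    trajectory at arbitrary event times, every random covariate must be
    either the time column itself or constant within each subject.
    """

    name: str
    fixed_covariates: Sequence[str]
    random_covariates: Sequence[str]
    time_column: str = "time"
    response_column: str | None = None

    def __post_init__(self):
        if len(self.fixed_covariates) < 1 or len(self.random_covariates) < 1:
            raise ValueError("each outcome needs >=1 fixed and >=1 random covariate")
        if self.response_column is None:
            self.response_column = self.name

    @property
    def p(self) -> int:
        return len(self.fixed_covariates)

    @property
    def r(self) -> int:
        return len(self.random_covariates)


@dataclass
class SubjectData:
    """All observed data for one subject.

    ``z_const[k]`` holds, for each random covariate of outcome ``k``, either
    ``None`` (the covariate is the measurement time) or its constant value
    for this subject, which is what lets ``z_at`` evaluate the random-effects
    design at event times that need not coincide with measurement times.
    """

    id: object
    times: list[np.ndarray]
    y: list[np.ndarray]
    X: list[np.ndarray]
    Z: list[np.ndarray]
    time: float
    event: int
    v: np.ndarray
    z_const: list[list[float | None]] = field(default_factory=list)

    @property
    def n_k(self) -> list[int]:
        return [len(t) for t in self.times]

    def z_at(self, k: int, t: float) -> np.ndarray:
        """Random-effects design row z_ik(t) for outcome ``k`` at time ``t``."""
        return np.array(
            [t if c is None else c for c in self.z_const[k]], dtype=float
        )


@dataclass
class JointDataset:
    """``n`` subjects, each with ``K`` outcome series and a survival record."""

    subjects: list[SubjectData]
    specs: list[OutcomeSpec]
    survival_covariates: list[str]
    balanced: bool = False

    def __post_init__(self):
        if len(self.subjects) < 1:
            raise ValueError("dataset needs at least one subject")

    @property
    def K(self) -> int:
        return len(self.specs)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return int(sum(s.event for s in self.subjects))

    @property
    def p_blocks(self) -> list[int]:
        return [s.p for s in self.specs]

    @property
    def r_blocks(self) -> list[int]:
        return [s.r for s in self.specs]

    @property
    def r(self) -> int:
        return sum(self.r_blocks)

    @property
    def q(self) -> int:
        return len(self.survival_covariates)

    def failure_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct observed failure times and their event multiplicities."""
        ev = np.array([s.time for s in self.subjects if s.event == 1])
        if ev.size == 0:
            return np.array([]), np.array([], dtype=int)
        t, d = np.unique(ev, return_counts=True)
        return t, d

    def to_tables(self, id_column: str = "id") -> tuple[list[pd.DataFrame], pd.DataFrame]:
        """Export back to long-format tables plus a survival table."""
        longs = []
        for k, spec in enumerate(self.specs):
            cols = {}
            ids, times, resp = [], [], []
            covcols: dict[str, list] = {
                c: [] for c in dict.fromkeys(
                    list(spec.fixed_covariates) + list(spec.random_covariates)
                )
                if c != spec.time_column
            }
            for s in self.subjects:
                nk = len(s.times[k])
                ids += [s.id] * nk
                times += list(s.times[k])
                resp += list(s.y[k])
                for c in covcols:
                    if c in spec.fixed_covariates:
                        j = list(spec.fixed_covariates).index(c)
                        covcols[c] += list(s.X[k][:, j])
                    else:
                        j = list(spec.random_covariates).index(c)
                        covcols[c] += list(s.Z[k][:, j])
            cols[id_column] = ids
            cols[spec.time_column] = times
            cols[spec.response_column] = resp
            cols.update(covcols)
            longs.append(pd.DataFrame(cols))
        surv = pd.DataFrame(
            {
                id_column: [s.id for s in self.subjects],
                "time": [s.time for s in self.subjects],
                "status": [s.event for s in self.subjects],
                **{
                    c: [s.v[j] for s in self.subjects]
                    for j, c in enumerate(self.survival_covariates)
                },
            }
        )
        return longs, surv


@dataclass
class ParameterSet:
    """Full parameter vector of the joint model.

    ``beta`` is the stacked fixed-effects vector, ``D`` the ``r x r``
    random-effects covariance (blocks ``D_kl`` in outcome-major order),
    ``sigma2`` the residual variances, ``gamma_v``/``gamma_y`` the hazard
    coefficients for baseline covariates and latent associations, and
    ``lambda0`` the nonparametric baseline hazard: increments at the
    distinct observed failure times.
    """

    beta: np.ndarray
    D: np.ndarray
    sigma2: np.ndarray
    gamma_v: np.ndarray
    gamma_y: np.ndarray
    lambda0_times: np.ndarray = field(default_factory=lambda: np.array([]))
    lambda0: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.gamma_v = np.atleast_1d(np.asarray(self.gamma_v, dtype=float))
        self.gamma_y = np.atleast_1d(np.asarray(self.gamma_y, dtype=float))
        self.lambda0_times = np.asarray(self.lambda0_times, dtype=float)
        self.lambda0 = np.asarray(self.lambda0, dtype=float)
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValueError("D must be symmetric")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")
        if self.lambda0_times.size > 1 and np.any(np.diff(self.lambda0_times) <= 0):
            raise ValueError("baseline-hazard times must be strictly increasing")

    def flat(self) -> np.ndarray:
        """Parameters excluding the baseline hazard: (beta, vech(D), sigma2, gamma)."""
        return np.concatenate(
            [self.beta, vech(self.D), self.sigma2, self.gamma_v, self.gamma_y]
        )

    def labels(self, dataset: JointDataset | None = None) -> list[str]:
        r = self.D.shape[0]
        if dataset is not None:
            bl = [
                f"beta_{k + 1}:{c}"
                for k, spec in enumerate(dataset.specs)
                for c in spec.fixed_covariates
            ]
            gv = [f"gamma_v:{c}" for c in dataset.survival_covariates]
        else:
            bl = [f"beta_{j}" for j in range(len(self.beta))]
            gv = [f"gamma_v{j + 1}" for j in range(len(self.gamma_v))]
        return (
            bl
            + vech_labels(r)
            + [f"sigma2_{k + 1}" for k in range(len(self.sigma2))]
            + gv
            + [f"gamma_y{k + 1}" for k in range(len(self.gamma_y))]
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.beta.copy(),
            self.D.copy(),
            self.sigma2.copy(),
            self.gamma_v.copy(),
            self.gamma_y.copy(),
            self.lambda0_times.copy(),
            self.lambda0.copy(),
        )

    def beta_blocks(self, p_blocks: Sequence[int]) -> list[np.ndarray]:
        out, pos = [], 0
        for p in p_blocks:
            out.append(self.beta[pos : pos + p])
            pos += p
        return out


@dataclass
class MCEMControl:
    """Tuning parameters of the Monte Carlo EM run.

    ``tol_rel``/``tol_denom`` are the relative-difference stopping constants
    (eps0, eps1) and ``tol_abs`` the absolute one (eps2).  The default
    ``hybrid`` criterion checks components with current magnitude below 0.01
    by absolute difference and the rest by relative difference: a pure
    relative rule is unstable for parameters near zero, whose iteration-to-
    iteration changes are Monte Carlo noise.  ``N0`` and ``burnin`` default
    to ``100*K`` when left as ``None``.  ``delta`` is the Monte Carlo growth
    divisor in ``N := N + floor(N/delta)``; ``consecutive`` the number of
    successive passes required before convergence is declared.
    """

    tol_rel: float = 0.005
    tol_denom: float = 0.001
    tol_abs: float = 0.005
    criterion: str = "hybrid"  # rel | abs | hybrid
    N0: int | None = None
    burnin: int | None = None
    delta: int = 3
    consecutive: int = 3
    max_N: int | None = None
    max_iter: int = 600
    gamma_update: str = "NR"  # NR | GN
    seed: int | None = None
    se_method: str = "empirical"  # empirical | bootstrap | none
    se_N_factor: int = 4

    def __post_init__(self):
        if min(self.tol_rel, self.tol_denom, self.tol_abs) <= 0:
            raise ValueError("tolerances must be positive")
        if self.criterion not in ("rel", "abs", "hybrid"):
            raise ValueError("criterion must be 'rel', 'abs' or 'hybrid'")
        if self.N0 is not None and self.N0 % 2:
            raise ValueError("N0 must be even (antithetic pairing)")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")
        if self.gamma_update not in ("NR", "GN"):
            raise ValueError("gamma_update must be 'NR' or 'GN'")

    def resolve(self, K: int) -> "MCEMControl":
        """Fill the K-dependent defaults (N0 and burn-in are 100*K)."""
        out = MCEMControl(**self.__dict__)
        if out.N0 is None:
            out.N0 = 100 * K
        if out.burnin is None:
            out.burnin = 100 * K
        return out


@dataclass
class FitResult:
    """Outcome of an MCEM fit (parameters, uncertainty, diagnostics)."""

    theta_hat: ParameterSet
    se: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    trace: pd.DataFrame
    converged: bool
    n_iter: int
    final_N: int
    labels: list[str]
    n_subjects: int = 0
    messages: list[str] = field(default_factory=list)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        est = self.theta_hat.flat()
        out = pd.DataFrame({"parameter": self.labels, "estimate": est})
        if self.se is not None:
            z = norm.ppf(0.5 + level / 2)
            out["se"] = self.se
            out["lower"] = est - z * self.se
            out["upper"] = est + z * self.se
        return out


def _read_table(source, delimiter: str = ",") -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep=delimiter)


def _subject_z_const(
    sub_rows: pd.DataFrame, spec: OutcomeSpec, global_const: dict
) -> list[float | None]:
    """Classify each random covariate as the time column or a constant."""
    out: list[float | None] = []
    for c in spec.random_covariates:
        if c == spec.time_column:
            out.append(None)
        elif len(sub_rows):
            vals = sub_rows[c].to_numpy(dtype=float)
            if np.ptp(vals) > 1e-12:
                raise ValueError(
                    f"random covariate {c!r} varies over time within subject "
                    f"{sub_rows.index[0]!r} but is not the time column; "
                    "it cannot be evaluated at event times"
                )
            out.append(float(vals[0]))
        else:
            out.append(global_const.get(c, np.nan))
    return out


def load_joint_dataset(
    long_tables,
    survival_table,
    specs: Sequence[OutcomeSpec],
    id_column: str = "id",
    survival_covariates: Sequence[str] | None = None,
    delimiter: str = ",",
) -> JointDataset:
    """Build a :class:`JointDataset` from long-format sources.

    ``long_tables`` is one table per outcome, or a single shared table when
    visit times coincide across outcomes.  The survival table must contain
    ``id_column``, ``time`` and ``status`` plus any baseline covariates.
    Blank responses and rows with missing covariates are dropped with a
    warning; duplicate (id, time) rows within one outcome are an error.
    """
    specs = list(specs)
    K = len(specs)
    if isinstance(long_tables, (pd.DataFrame, str)) or hasattr(long_tables, "read"):
        long_tables = [long_tables] * K
    longs = [_read_table(t, delimiter) for t in long_tables]
    if len(longs) == 1 and K > 1:
        longs = longs * K
    if len(longs) != K:
        raise ValueError(f"expected {K} long tables, got {len(longs)}")
    surv = _read_table(survival_table, delimiter)
    for col in (id_column, "time", "status"):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if survival_covariates is None:
        survival_covariates = [
            c for c in surv.columns if c not in (id_column, "time", "status")
        ]
    survival_covariates = list(survival_covariates)

    surv_ids = list(surv[id_column])
    if len(set(surv_ids)) != len(surv_ids):
        raise ValueError("duplicate subject ids in survival table")
    id_index = {i: j for j, i in enumerate(surv_ids)}

    n_dropped_resp = 0
    n_dropped_cov = 0
    per_outcome_rows: list[dict] = []
    for k, (tab, spec) in enumerate(zip(longs, specs)):
        needed = {id_column, spec.time_column, spec.response_column} | set(
            spec.fixed_covariates
        ) | set(spec.random_covariates)
        missing = needed - set(tab.columns)
        if missing:
            raise ValueError(
                f"outcome {spec.name!r}: missing column(s) {sorted(missing)}"
            )
        unknown = set(tab[id_column]) - set(surv_ids)
        if unknown:
            raise ValueError(
                f"outcome {spec.name!r}: id {sorted(unknown, key=str)[0]!r} "
                "not present in survival table"
            )
        resp = pd.to_numeric(tab[spec.response_column], errors="coerce")
        bad = resp.isna() & tab[spec.response_column].notna()
        if bad.any():
            raise ValueError(
                f"outcome {spec.name!r}: non-numeric response at row "
                f"{int(np.flatnonzero(bad)[0]) + 2} (1-based incl. header)"
            )
        tab = tab.assign(**{spec.response_column: resp})
        keep = resp.notna()
        n_dropped_resp += int((~keep).sum())
        tab = tab[keep]
        covcols = list(
            dict.fromkeys(
                [spec.time_column]
                + list(spec.fixed_covariates)
                + list(spec.random_covariates)
            )
        )
        for c in covcols:
            tab = tab.assign(**{c: pd.to_numeric(tab[c], errors="coerce")})
        ok = tab[covcols].notna().all(axis=1)
        n_dropped_cov += int((~ok).sum())
        tab = tab[ok]
        if np.any(tab[spec.time_column].to_numpy() < 0):
            raise ValueError(f"outcome {spec.name!r}: negative measurement time")
        dup = tab.duplicated(subset=[id_column, spec.time_column])
        if dup.any():
            row = tab[dup].iloc[0]
            raise ValueError(
                f"outcome {spec.name!r}: duplicate (id, time) = "
                f"({row[id_column]!r}, {row[spec.time_column]}) "
            )
        tab = tab.sort_values([id_column, spec.time_column], kind="stable")
        global_const = {
            c: float(tab[c].iloc[0])
            for c in spec.random_covariates
            if c != spec.time_column
            and len(tab)
            and np.ptp(tab[c].to_numpy(dtype=float)) <= 1e-12
        }
        per_outcome_rows.append(
            {"tab": tab, "spec": spec, "global_const": global_const}
        )

    if n_dropped_resp:
        warnings.warn(f"dropped {n_dropped_resp} rows with missing responses")
    if n_dropped_cov:
        warnings.warn(f"dropped {n_dropped_cov} rows with missing covariates")

    subjects: list[SubjectData] = []
    balanced = True
    for sid in surv_ids:
        row = surv.iloc[id_index[sid]]
        T_i = float(row["time"])
        if T_i < 0:
            raise ValueError(f"subject {sid!r}: negative survival time")
        delta_i = int(row["status"])
        if delta_i not in (0, 1):
            raise ValueError(f"subject {sid!r}: status must be 0/1")
        v_i = np.array([float(row[c]) for c in survival_covariates])
        times, ys, Xs, Zs, zconst = [], [], [], [], []
        for entry in per_outcome_rows:
            spec = entry["spec"]
            sub = entry["tab"][entry["tab"][id_column] == sid]
            times.append(sub[spec.time_column].to_numpy(dtype=float))
            ys.append(sub[spec.response_column].to_numpy(dtype=float))
            Xs.append(sub[list(spec.fixed_covariates)].to_numpy(dtype=float))
            Zs.append(sub[list(spec.random_covariates)].to_numpy(dtype=float))
            sub_idx = sub.copy()
            sub_idx.index = [sid] * len(sub)
            zconst.append(_subject_z_const(sub_idx, spec, entry["global_const"]))
        if balanced and K > 1:
            t0 = np.sort(times[0])
            for t in times[1:]:
                if len(t) != len(t0) or not np.array_equal(np.sort(t), t0):
                    balanced = False
                    break
        subjects.append(
            SubjectData(sid, times, ys, Xs, Zs, T_i, delta_i, v_i, zconst)
        )
    if K == 1:
        balanced = True
    return JointDataset(subjects, specs, survival_covariates, balanced)


def assemble_designs(dataset: JointDataset) -> list[dict]:
    """Per-subject stacked design structures.

    Returns for each subject a dict with the direct-sum fixed design ``X``
    (sum(n_ik) x sum(p_k)), random design ``Z`` (sum(n_ik) x sum(r_k)), the
    stacked response ``y`` and the per-outcome row counts ``n_k``.  Row and
    column order is outcome-major, matching beta/b stacking.
    """
    out = []
    for s in dataset.subjects:
        Xs = [
            X if X.size else np.zeros((0, spec.p))
            for X, spec in zip(s.X, dataset.specs)
        ]
        Zs = [
            Z if Z.size else np.zeros((0, spec.r))
            for Z, spec in zip(s.Z, dataset.specs)
        ]
        out.append(
            {
                "id": s.id,
                "X": block_diag(*Xs),
                "Z": block_diag(*Zs),
                "y": np.concatenate(s.y) if s.y else np.array([]),
                "n_k": s.n_k,
            }
        )
    return out


def validate_dataset(dataset: JointDataset) -> dict:
    """Sanity report for a joint dataset (raises if the hazard is unidentifiable)."""
    if dataset.n_events == 0:
        raise ValueError(
            "dataset contains no events; the baseline hazard is unidentifiable"
        )
    after_event = 0
    zero_measure = []
    for s in dataset.subjects:
        if sum(s.n_k) == 0:
            zero_measure.append(s.id)
        after_event += int(sum((t > s.time).sum() for t in s.times))
    warnings_list = []
    if after_event:
        warnings_list.append(
            f"{after_event} measurement(s) recorded after the observed event/"
            "censoring time (retained for fitting)"
        )
    if zero_measure:
        warnings_list.append(
            f"{len(zero_measure)} subject(s) with zero longitudinal measurements"
        )
    for w in warnings_list:
        warnings.warn(w)
    return {
        "n_subjects": dataset.n,
        "n_events": dataset.n_events,
        "n_measurements": [
            int(sum(s.n_k[k] for s in dataset.subjects)) for k in range(dataset.K)
        ],
        "n_after_event_time": after_event,
        "subjects_without_measurements": zero_measure,
        "balanced": bool(dataset.balanced),
        "warnings": warnings_list,
    }
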