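"""Condition-regression DDM fitting for gate-switch effects.

The behavioral model lets decision threshold ``a`` and drift ``v`` vary with
the 2 (WM state) x 2 (input switch) x 2 (output switch) x 2 (response
switch) crossing plus an additive updating-frequency term, all relative to
the maintenance/all-repeat reference cell::

    a ~ a_mr + update_freq + (state x input x output x response)   [15 cells]
    v ~ v_mr + update_freq + (state x input x output x response)

Non-decision time is a single free per-subject parameter.  Two estimation
routes are provided: a fast per-subject maximum-likelihood path
(:func:`fit_mle`) and a hierarchical Bayesian path
(:func:`fit_hierarchical`, Metropolis-within-Gibbs with normal random
effects across subjects), plus the usual MCMC companions — Gelman-Rubin
R-hat, DIC, and posterior-predictive simulation with signed-RT quantiles.

Threshold positivity in the hierarchical model is guaranteed by a log link
on ``a``'s linear predictor; identity-scale cell effects are recovered by
transforming posterior draws, so reported intervals stay valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ddm import DDMParams, simulate, _loglik_kernel
from .task import TrialSequence

__all__ = [
    "CELL_NAMES",
    "REFERENCE_CELL",
    "cell_name",
    "assign_cells",
    "build_design",
    "RegressionSpec",
    "simulate_behavior",
    "FitResult",
    "fit_mle",
    "SamplerSettings",
    "PosteriorSamples",
    "fit_hierarchical",
    "gelman_rubin",
    "dic",
    "posterior_predictive",
    "PPCResult",
]

_EPS = 1e-7  # series truncation tolerance for all likelihood evaluations


def cell_name(wm_state: str, input_switch: bool, output_switch: bool,
              response_switch: bool) -> str:
    st = "upd" if wm_state == "updating" else "mnt"
    return (
        f"{st}"
        f".i{'S' if input_switch else 'R'}"
        f".o{'S' if output_switch else 'R'}"
        f".r{'S' if response_switch else 'R'}"
    )


#: All 16 state x switch cells in canonical order; the first is the
#: maintenance/all-repeat reference (intercept) cell.
CELL_NAMES: list[str] = [
    cell_name(st, i, o, r)
    for st in ("maintenance", "updating")
    for i in (False, True)
    for o in (False, True)
    for r in (False, True)
]
REFERENCE_CELL = CELL_NAMES[0]


def assign_cells(seq: TrialSequence) -> pd.Series:
    """Cell name per trial; NA where any switch label is undefined."""
    t = seq.table
    out = []
    for st, i, o, r in zip(
        t["wm_state"], t["input_switch"], t["output_switch"], t["response_switch"]
    ):
        if pd.isna(i) or pd.isna(o) or pd.isna(r):
            out.append(pd.NA)
        else:
            out.append(cell_name(st, bool(i), bool(o), bool(r)))
    return pd.Series(out, index=t.index, dtype=object)


def build_design(seq: TrialSequence) -> pd.DataFrame:
    """Trial x coefficient indicator matrix for the condition regression.

    Columns: ``update_freq`` (1 in the frequent-updating phase) followed by
    the 15 non-reference cell indicators.  Rows cover labeled, non-excluded
    trials; trials with undefined switch labels are dropped with a log entry.
    """
    t = seq.table
    cells = assign_cells(seq)
    keep = cells.notna()
    if "excluded" in t.columns:
        keep &= ~t["excluded"]
    n_drop = int((cells.isna()).sum())
    if n_drop:
        warnings.warn(f"build_design: dropped {n_drop} trial(s) with undefined switch labels")
    cells = cells[keep]
    X = pd.DataFrame(0, index=cells.index, columns=["update_freq"] + CELL_NAMES[1:], dtype=int)
    X["update_freq"] = (t.loc[keep, "update_frequency_phase"] == "frequent").astype(int)
    for name in CELL_NAMES[1:]:
        X.loc[cells == name, name] = 1
    return X


# ---------------------------------------------------------------------------
# generative regression spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionSpec:
    """Ground-truth (or template) condition regression on identity scale.

    ``a_cell``/``v_cell`` map non-reference cell names to offsets from the
    maintenance/all-repeat intercepts; missing cells default to 0.
    """

    a_mr: float = 1.5
    v_mr: float = 2.0
    t: float = 0.3
    a_cell: dict[str, float] = field(default_factory=dict)
    v_cell: dict[str, float] = field(default_factory=dict)
    a_freq: float = 0.0
    v_freq: float = 0.0

    def params_for(self, cell: str, frequent: bool) -> DDMParams:
        a = self.a_mr + self.a_cell.get(cell, 0.0) + (self.a_freq if frequent else 0.0)
        v = self.v_mr + self.v_cell.get(cell, 0.0) + (self.v_freq if frequent else 0.0)
        if a <= 0:
            raise ValueError(f"spec predicts non-positive threshold in cell {cell}")
        return DDMParams(a=a, v=v, t=self.t)


def simulate_behavior(seq: TrialSequence, spec: RegressionSpec, seed: int,
                      dt: float = 1e-3) -> TrialSequence:
    """Fill choice/rt/accuracy by sampling the DDM cell-by-cell.

    Accuracy coding: the upper boundary is the correct response, so
    ``choice`` is the trial's correct response when the upper boundary is
    hit and the alternative response otherwise.  Trials with undefined
    switch labels (the session's first trial) draw from the reference cell.
    """
    t = seq.table.copy()
    cells = assign_cells(seq).fillna(REFERENCE_CELL)
    frequent = t["update_frequency_phase"] == "frequent"
    rt = np.full(len(t), np.nan)
    correct = np.zeros(len(t), dtype=bool)
    ss = np.random.SeedSequence(seed)
    groups = sorted(set(zip(cells, frequent)))
    child_seeds = {g: int(s.generate_state(1)[0] % (2**31 - 1))
                   for g, s in zip(groups, ss.spawn(len(groups)))}
    for (cell, freq), idx in t.groupby([cells, frequent], sort=True).groups.items():
        params = spec.params_for(cell, freq)
        sam = simulate(params, len(idx), dt=dt, seed=child_seeds[(cell, freq)])
        rt[t.index.get_indexer(idx)] = sam["rt"].to_numpy()
        correct[t.index.get_indexer(idx)] = (sam["choice"] == "upper").to_numpy()

    other = {"same": "different", "different": "same"}
    choice = []
    for cr, ok, r in zip(t["correct_response"], correct, rt):
        if pd.isna(cr) or np.isnan(r):
            choice.append("omission")
        else:
            choice.append(cr if ok else other[cr])
    t["choice"] = choice
    t["rt"] = rt
    t["accuracy"] = correct & pd.notna(t["correct_response"]).to_numpy()
    return TrialSequence(table=t, config=seq.config)


# ---------------------------------------------------------------------------
# maximum-likelihood path
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Coefficient table plus fit diagnostics.

    ``coefficients`` rows: family (``a``/``v``/``t``), name, estimate,
    ci_low, ci_high.  MLE intervals are Wald (observed information);
    hierarchical intervals are 95% highest-density intervals of the group
    mean.
    """

    coefficients: pd.DataFrame
    loglik: float | None = None
    dic: float | None = None
    max_rhat: float | None = None
    converged: bool = True
    messages: list[str] = field(default_factory=list)

    def coef(self, family: str, name: str) -> float:
        m = self.coefficients
        row = m[(m["family"] == family) & (m["name"] == name)]
        if len(row) != 1:
            raise KeyError(f"coefficient ({family}, {name}) not found")
        return float(row["estimate"].iloc[0])

    def to_json(self, path) -> None:
        import json

        payload = {
            "coefficients": self.coefficients.to_dict(orient="records"),
            "loglik": self.loglik, "dic": self.dic, "max_rhat": self.max_rhat,
            "converged": self.converged, "messages": self.messages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _nll_group(rts, is_upper, a, v, t):
    ll = _loglik_kernel(rts, is_upper, a, v, t, 0.5, _EPS)
    return np.inf if ll == -np.inf else -ll


def _grouped_trials(seq: TrialSequence):
    """Retained trials grouped by (cell, frequent); arrays per group."""
    t = seq.table
    cells = assign_cells(seq)
    keep = cells.notna() & t["choice"].isin(["same", "different"])
    if "excluded" in t.columns:
        keep &= ~t["excluded"]
    sub = t.loc[keep]
    cells = cells.loc[keep]
    freq = (sub["update_frequency_phase"] == "frequent").to_numpy()
    rts = sub["rt"].to_numpy(dtype=float)
    is_up = sub["accuracy"].to_numpy(dtype=bool)
    groups = []
    for (cell, fr), idx in sub.groupby([cells, freq], sort=True).groups.items():
        loc = sub.index.get_indexer(idx)
        groups.append((cell, bool(fr), rts[loc], is_up[loc]))
    return groups


def _fit_one_group(rts, is_upper, seed, n_starts=2, t_fixed=None):
    """(a, v, t) or (a, v | t) MLE for one homogeneous condition group."""
    rng = np.random.default_rng(seed)
    min_rt = float(rts.min())
    acc = float(is_upper.mean())
    v0 = np.clip(4.0 * (acc - 0.5), -4.0, 4.0) + 0.5
    a0, t0 = 1.5, 0.85 * min_rt

    if t_fixed is None:
        def nll(x):
            a, v, tf = np.exp(x[0]), x[1], x[2]
            if not 0.0 < tf < min_rt:
                return np.inf
            return _nll_group(rts, is_upper, a, v, tf)
        x0s = [np.array([np.log(a0), v0, t0])]
    else:
        def nll(x):
            return _nll_group(rts, is_upper, np.exp(x[0]), x[1], t_fixed)
        x0s = [np.array([np.log(a0), v0])]
    for _ in range(n_starts - 1):
        x0s.append(x0s[0] + rng.normal(0, [0.3, 0.5, 0.05][: len(x0s[0])]))

    best = None
    for x0 in x0s:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    a, v = float(np.exp(best.x[0])), float(best.x[1])
    t = float(best.x[2]) if t_fixed is None else float(t_fixed)
    return a, v, t, float(best.fun), bool(best.success)


def _group_av_hessian(rts, is_upper, a, v, t, h=1e-4):
    """Observed information of (a, v) at the optimum, central differences."""
    def f(da, dv):
        return _nll_group(rts, is_upper, a + da, v + dv, t)
    f0 = f(0, 0)
    H = np.empty((2, 2))
    H[0, 0] = (f(h, 0) - 2 * f0 + f(-h, 0)) / h**2
    H[1, 1] = (f(0, h) - 2 * f0 + f(0, -h)) / h**2
    H[0, 1] = H[1, 0] = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h**2)
    return H


def fit_mle(seq: TrialSequence, include_freq: bool = True, n_starts: int = 2,
            seed: int = 0, min_trials_per_cell: int = 20) -> FitResult:
    """Per-subject maximum-likelihood fit of the condition regression.

    Profile strategy exploiting that the cells partition trials: each
    (cell, frequency) group is fit on its own with multi-start Nelder-Mead,
    non-decision time is consolidated to the trial-weighted median and the
    per-group (a, v) re-optimized at the shared ``t``; coefficients are then
    the (weighted) least-squares projection of group estimates onto the
    intercept + cells (+ frequency) basis — exact whenever the design is
    saturated.
    """
    groups = _grouped_trials(seq)
    if not groups:
        raise ValueError("no retained trials with behavior to fit")
    msgs = []
    small = [(c, f) for c, f, r, _ in groups if r.size < min_trials_per_cell]
    if small:
        msgs.append(f"cells with fewer than {min_trials_per_cell} trials: {small}")
        warnings.warn(msgs[-1])

    rng = np.random.default_rng(seed)
    stage1 = [
        _fit_one_group(r, u, int(rng.integers(2**31 - 1)), n_starts=n_starts)
        for _, _, r, u in groups
    ]
    n_g = np.array([r.size for _, _, r, _ in groups], dtype=float)
    t_hat = float(np.median(np.repeat([s[2] for s in stage1], n_g.astype(int))))
    t_hat = min(t_hat, 0.999 * min(float(r.min()) for _, _, r, _ in groups))

    a_g, v_g, var_a, var_v, nll_total, ok = [], [], [], [], 0.0, True
    for (cell, fr, r, u), s1 in zip(groups, stage1):
        a, v, _, fun, succ = _fit_one_group(
            r, u, int(rng.integers(2**31 - 1)), n_starts=1, t_fixed=t_hat
        )
        ok &= succ
        nll_total += fun
        a_g.append(a)
        v_g.append(v)
        H = _group_av_hessian(r, u, a, v, t_hat)
        try:
            C = np.linalg.inv(H)
            var_a.append(max(C[0, 0], 0.0))
            var_v.append(max(C[1, 1], 0.0))
        except np.linalg.LinAlgError:
            var_a.append(np.nan)
            var_v.append(np.nan)

    # project group estimates onto the coefficient basis
    cells_in = [c for c, _, _, _ in groups]
    freq_in = [fr for _, fr, _, _ in groups]
    coef_cells = [c for c in CELL_NAMES[1:] if c in cells_in]
    names = ["intercept"] + coef_cells + (["update_freq"] if include_freq and len(set(freq_in)) > 1 else [])
    G = np.zeros((len(groups), len(names)))
    G[:, 0] = 1.0
    for j, c in enumerate(coef_cells, start=1):
        G[:, j] = [cc == c for cc in cells_in]
    if names[-1] == "update_freq":
        G[:, -1] = freq_in

    W = np.diag(n_g)

    def project(y, var):
        A = G.T @ W @ G
        theta = np.linalg.solve(A, G.T @ W @ np.asarray(y))
        M = np.linalg.solve(A, G.T @ W)
        cov = M @ np.diag(var) @ M.T
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return theta, se

    th_a, se_a = project(a_g, var_a)
    th_v, se_v = project(v_g, var_v)

    rows = []
    for fam, th, se in (("a", th_a, se_a), ("v", th_v, se_v)):
        for nm, est, s in zip(names, th, se):
            nm_out = f"{fam}_mr" if nm == "intercept" else nm
            rows.append(dict(family=fam, name=nm_out, estimate=est,
                             ci_low=est - 1.96 * s, ci_high=est + 1.96 * s))
    rows.append(dict(family="t", name="t", estimate=t_hat, ci_low=np.nan, ci_high=np.nan))
    return FitResult(coefficients=pd.DataFrame(rows), loglik=-nll_total,
                     converged=ok, messages=msgs)


# ---------------------------------------------------------------------------
# hierarchical Bayesian path
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC schedule.  Defaults: 4 chains of 3000 draws, the first 1000
    discarded as burn-in and every second retained thereafter."""

    chains: int = 4
    draws: int = 3000
    burn_in: int = 1000
    thin: int = 2

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("at least one chain required")
        if self.burn_in >= self.draws:
            raise ValueError("burn_in must be smaller than draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_draws(self) -> int:
        return (self.draws - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws.

    ``group``: parameter name -> (chains, draws) array for group-level means
    and SDs.  ``subject``: family -> (chains, draws, n_subjects, dim) array
    of subject-level coefficients (``theta_a`` on the log scale, ``theta_v``
    identity, ``t`` seconds).
    """

    group: dict[str, np.ndarray]
    subject: dict[str, np.ndarray]
    settings: SamplerSettings
    coef_names: list[str]
    subject_ids: list

    @property
    def retained_draws_per_chain(self) -> int:
        return next(iter(self.group.values())).shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for grp, arrs in (("group", self.group), ("subject", self.subject)):
                g = f.create_group(grp)
                for name, arr in arrs.items():
                    g.create_dataset(name, data=arr)
            f.attrs["chains"] = self.settings.chains
            f.attrs["draws"] = self.settings.draws
            f.attrs["burn_in"] = self.settings.burn_in
            f.attrs["thin"] = self.settings.thin
            f.attrs["coef_names"] = [str(n) for n in self.coef_names]
            f.attrs["subject_ids"] = [str(s) for s in self.subject_ids]

    @classmethod
    def from_hdf5(cls, path) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as f:
            settings = SamplerSettings(
                chains=int(f.attrs["chains"]), draws=int(f.attrs["draws"]),
                burn_in=int(f.attrs["burn_in"]), thin=int(f.attrs["thin"]),
            )
            return cls(
                group={k: v[()] for k, v in f["group"].items()},
                subject={k: v[()] for k, v in f["subject"].items()},
                settings=settings,
                coef_names=list(f.attrs["coef_names"]),
                subject_ids=list(f.attrs["subject_ids"]),
            )


# priors: weakly-informative normals on group means; inverse-gamma on
# random-effect variances
_PRIOR_MU = {"a0": (np.log(1.5), 1.0), "a": (0.0, 1.0),
             "v0": (2.0, 2.0), "v": (0.0, 2.0), "t": (0.3, 0.2)}
_PRIOR_TAU2 = (2.0, 0.1)  # InvGamma(shape, scale)


class _Subject:
    """Per-subject data and cached likelihood state for the sampler."""

    def __init__(self, seq: TrialSequence, coef_cells, include_freq):
        groups = _grouped_trials(seq)
        self.rts = [g[2] for g in groups]
        self.is_up = [g[3] for g in groups]
        self.min_rt = min(float(r.min()) for r in self.rts)
        names = ["intercept"] + coef_cells + (["update_freq"] if include_freq else [])
        G = np.zeros((len(groups), len(names)))
        G[:, 0] = 1.0
        for j, c in enumerate(coef_cells, start=1):
            G[:, j] = [g[0] == c for g in groups]
        if include_freq:
            G[:, -1] = [g[1] for g in groups]
        self.G = G
        self.p = len(names)
        # groups touched by each coefficient
        self.affected = [np.flatnonzero(G[:, j] != 0.0) for j in range(self.p)]

    def group_nll(self, g, a_g, v_g, t):
        ll = _loglik_kernel(self.rts[g], self.is_up[g], a_g, v_g, t, 0.5, _EPS)
        return np.inf if ll == -np.inf else -ll

    def all_nll(self, theta_a, theta_v, t):
        a = np.exp(self.G @ theta_a)
        v = self.G @ theta_v
        return np.array([self.group_nll(g, a[g], v[g], t) for g in range(len(self.rts))])


def fit_hierarchical(
    trials_by_subject: dict, settings: SamplerSettings = SamplerSettings(),
    include_freq: bool = False, seed: int = 0,
) -> tuple[PosteriorSamples, FitResult]:
    """Hierarchical Bayesian fit of the condition regression.

    Metropolis-within-Gibbs: per-coordinate random-walk Metropolis on each
    subject's coefficients (log-threshold, drift, non-decision time) with
    step sizes adapted during burn-in, and conjugate Gibbs updates for the
    normal group means and inverse-gamma random-effect variances.
    Deterministic given ``seed``.  Cells absent from every subject are
    dropped from the coefficient basis.
    """
    if settings.chains < 2:
        warnings.warn("fewer than 2 chains: R-hat will not be computable")
    ids = list(trials_by_subject)
    present = set()
    for sid in ids:
        present |= {c for c, *_ in _grouped_trials(trials_by_subject[sid])}
    coef_cells = [c for c in CELL_NAMES[1:] if c in present]
    subs = [_Subject(trials_by_subject[sid], coef_cells, include_freq) for sid in ids]
    p = subs[0].p
    names = ["intercept"] + coef_cells + (["update_freq"] if include_freq else [])
    S = len(subs)

    n_ret = settings.retained_draws
    group_store: dict[str, np.ndarray] = {}
    for j, nm in enumerate(names):
        for fam in ("a", "v"):
            group_store[f"mu_{fam}[{nm}]"] = np.empty((settings.chains, n_ret))
            group_store[f"tau_{fam}[{nm}]"] = np.empty((settings.chains, n_ret))
    group_store["mu_t"] = np.empty((settings.chains, n_ret))
    group_store["tau_t"] = np.empty((settings.chains, n_ret))
    subj_store = {
        "theta_a": np.empty((settings.chains, n_ret, S, p)),
        "theta_v": np.empty((settings.chains, n_ret, S, p)),
        "t": np.empty((settings.chains, n_ret, S)),
    }

    root = np.random.SeedSequence(seed)
    for chain, chain_ss in enumerate(root.spawn(settings.chains)):
        rng = np.random.default_rng(chain_ss)
        # initial values: data-agnostic centers plus chain jitter
        th_a = np.tile(np.r_[np.log(1.5), np.zeros(p - 1)], (S, 1)) + rng.normal(0, 0.05, (S, p))
        th_v = np.tile(np.r_[1.0, np.zeros(p - 1)], (S, 1)) + rng.normal(0, 0.1, (S, p))
        t_s = np.array([0.7 * sub.min_rt for sub in subs]) * rng.uniform(0.9, 1.0, S)
        mu_a, tau_a = th_a.mean(0), np.full(p, 0.3)
        mu_v, tau_v = th_v.mean(0), np.full(p, 0.3)
        mu_t, tau_t = float(t_s.mean()), 0.1

        nll = [sub.all_nll(th_a[s], th_v[s], t_s[s]) for s, sub in enumerate(subs)]
        step_a = np.full((S, p), 0.08)
        step_v = np.full((S, p), 0.15)
        step_t = np.full(S, 0.02)
        acc_a = np.zeros((S, p)); acc_v = np.zeros((S, p)); acc_t = np.zeros(S)
        n_since = 0
        kept = 0

        for it in range(settings.draws):
            for s, sub in enumerate(subs):
                a_lin = sub.G @ th_a[s]
                v_lin = sub.G @ th_v[s]
                # threshold coefficients (log scale)
                for j in range(p):
                    prop = th_a[s, j] + step_a[s, j] * rng.standard_normal()
                    aff = sub.affected[j]
                    d = prop - th_a[s, j]
                    new_nll = np.array([
                        sub.group_nll(g, np.exp(a_lin[g] + d * sub.G[g, j]), v_lin[g], t_s[s])
                        for g in aff
                    ])
                    lp = (
                        -(new_nll.sum() - nll[s][aff].sum())
                        - ((prop - mu_a[j]) ** 2 - (th_a[s, j] - mu_a[j]) ** 2) / (2 * tau_a[j] ** 2)
                    )
                    if np.log(rng.random()) < lp:
                        th_a[s, j] = prop
                        a_lin[aff] += d * sub.G[aff, j]
                        nll[s][aff] = new_nll
                        acc_a[s, j] += 1
                # drift coefficients
                for j in range(p):
                    prop = th_v[s, j] + step_v[s, j] * rng.standard_normal()
                    aff = sub.affected[j]
                    d = prop - th_v[s, j]
                    new_nll = np.array([
                        sub.group_nll(g, np.exp(a_lin[g]), v_lin[g] + d * sub.G[g, j], t_s[s])
                        for g in aff
                    ])
                    lp = (
                        -(new_nll.sum() - nll[s][aff].sum())
                        - ((prop - mu_v[j]) ** 2 - (th_v[s, j] - mu_v[j]) ** 2) / (2 * tau_v[j] ** 2)
                    )
                    if np.log(rng.random()) < lp:
                        th_v[s, j] = prop
                        v_lin[aff] += d * sub.G[aff, j]
                        nll[s][aff] = new_nll
                        acc_v[s, j] += 1
                # non-decision time
                prop = t_s[s] + step_t[s] * rng.standard_normal()
                if 0.0 < prop < sub.min_rt:
                    new_nll = sub.all_nll(th_a[s], th_v[s], prop)
                    lp = (
                        -(new_nll.sum() - nll[s].sum())
                        - ((prop - mu_t) ** 2 - (t_s[s] - mu_t) ** 2) / (2 * tau_t ** 2)
                    )
                    if np.log(rng.random()) < lp:
                        t_s[s] = prop
                        nll[s] = new_nll
                        acc_t[s] += 1

            # conjugate group updates
            for j in range(p):
                for (th, mu, tau, key) in ((th_a, mu_a, tau_a, "a"), (th_v, mu_v, tau_v, "v")):
                    m0, s0 = _PRIOR_MU[f"{key}0"] if j == 0 else _PRIOR_MU[key]
                    prec = 1.0 / s0**2 + S / tau[j] ** 2
                    mean = (m0 / s0**2 + th[:, j].sum() / tau[j] ** 2) / prec
                    mu[j] = mean + rng.standard_normal() / np.sqrt(prec)
                    a0, b0 = _PRIOR_TAU2
                    sse = float(((th[:, j] - mu[j]) ** 2).sum())
                    tau[j] = np.sqrt(1.0 / rng.gamma(a0 + S / 2.0, 1.0 / (b0 + sse / 2.0)))
            m0, s0 = _PRIOR_MU["t"]
            prec = 1.0 / s0**2 + S / tau_t**2
            mu_t = (m0 / s0**2 + t_s.sum() / tau_t**2) / prec + rng.standard_normal() / np.sqrt(prec)
            a0, b0 = _PRIOR_TAU2
            tau_t = float(np.sqrt(1.0 / rng.gamma(a0 + S / 2.0, 1.0 / (b0 + ((t_s - mu_t) ** 2).sum() / 2.0))))

            n_since += 1
            if it < settings.burn_in and n_since == 50:
                for arr, acc in ((step_a, acc_a), (step_v, acc_v), (step_t, acc_t)):
                    rate = acc / n_since
                    arr *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    acc[...] = 0.0
                n_since = 0
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 and kept < n_ret:
                for j, nm in enumerate(names):
                    group_store[f"mu_a[{nm}]"][chain, kept] = mu_a[j]
                    group_store[f"tau_a[{nm}]"][chain, kept] = tau_a[j]
                    group_store[f"mu_v[{nm}]"][chain, kept] = mu_v[j]
                    group_store[f"tau_v[{nm}]"][chain, kept] = tau_v[j]
                group_store["mu_t"][chain, kept] = mu_t
                group_store["tau_t"][chain, kept] = tau_t
                subj_store["theta_a"][chain, kept, :, :] = th_a
                subj_store["theta_v"][chain, kept, :, :] = th_v
                subj_store["t"][chain, kept, :] = t_s
                kept += 1

    samples = PosteriorSamples(group=group_store, subject=subj_store,
                               settings=settings, coef_names=names, subject_ids=ids)
    result = _summarize_hierarchical(samples)
    return samples, result


def _hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    x = np.sort(np.asarray(draws).ravel())
    n = len(x)
    m = max(1, int(np.floor(mass * n)))
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def _summarize_hierarchical(samples: PosteriorSamples) -> FitResult:
    rows = []
    names = samples.coef_names
    mu_a0 = samples.group["mu_a[intercept]"]
    for nm in names:
        for fam in ("a", "v"):
            d = samples.group[f"mu_{fam}[{nm}]"]
            lo, hi = _hdi(d)
            out_nm = f"{fam}_mr" if nm == "intercept" else nm
            rows.append(dict(family=fam, name=out_nm, estimate=float(d.mean()),
                             ci_low=lo, ci_high=hi))
        # identity-scale threshold effect, transformed draw-by-draw
        if nm != "intercept":
            eff = np.exp(mu_a0 + samples.group[f"mu_a[{nm}]"]) - np.exp(mu_a0)
            lo, hi = _hdi(eff)
            rows.append(dict(family="a_identity", name=nm, estimate=float(eff.mean()),
                             ci_low=lo, ci_high=hi))
    d = samples.group["mu_t"]
    lo, hi = _hdi(d)
    rows.append(dict(family="t", name="t", estimate=float(d.mean()), ci_low=lo, ci_high=hi))

    rhat = gelman_rubin(samples) if samples.group["mu_t"].shape[0] >= 2 else None
    max_rhat = float(rhat.max()) if rhat is not None else None
    res = FitResult(coefficients=pd.DataFrame(rows), max_rhat=max_rhat)
    if max_rhat is not None and max_rhat > 1.1:
        res.converged = False
        res.messages.append(f"max R-hat {max_rhat:.3f} > 1.1: chains have not converged")
        warnings.warn(res.messages[-1])
    return res


def gelman_rubin(samples) -> pd.Series:
    """Potential scale reduction R-hat per group-level parameter.

    ``samples`` is a :class:`PosteriorSamples` or a mapping of parameter
    name to (chains, draws) arrays.  Requires >= 2 chains and >= 10 draws.
    """
    group = samples.group if isinstance(samples, PosteriorSamples) else dict(samples)
    out = {}
    for name, arr in group.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"{name}: expected (chains, draws) array")
        m, n = arr.shape
        if m < 2:
            raise ValueError("R-hat requires at least 2 chains")
        if n < 10:
            raise ValueError("R-hat requires at least 10 draws per chain")
        W = arr.var(axis=1, ddof=1).mean()
        B = n * arr.mean(axis=1).var(ddof=1)
        if W == 0.0:
            out[name] = 1.0 if B == 0.0 else np.inf
            continue
        var_plus = (n - 1) / n * W + B / n
        out[name] = float(np.sqrt(var_plus / W))
    return pd.Series(out)


def _deviance(subs: list[_Subject], th_a, th_v, t_s) -> float:
    total = 0.0
    for s, sub in enumerate(subs):
        total += sub.all_nll(th_a[s], th_v[s], t_s[s]).sum()
    return 2.0 * total


def dic(samples: PosteriorSamples, trials_by_subject: dict,
        include_freq: bool = False, stride: int = 1) -> float:
    """Deviance information criterion DIC = mean deviance + p_D, with
    p_D = mean deviance - deviance at the posterior-mean parameters.

    ``stride`` subsamples retained draws for speed; DIC is deterministic
    given the stored draws and stride.
    """
    coef_cells = [c for c in samples.coef_names if c not in ("intercept", "update_freq")]
    subs = [_Subject(trials_by_subject[sid], coef_cells, "update_freq" in samples.coef_names)
            for sid in samples.subject_ids]
    th_a = samples.subject["theta_a"]
    th_v = samples.subject["theta_v"]
    t_s = samples.subject["t"]
    C, N = th_a.shape[0], th_a.shape[1]
    devs = []
    for c in range(C):
        for i in range(0, N, stride):
            devs.append(_deviance(subs, th_a[c, i], th_v[c, i], t_s[c, i]))
    mean_dev = float(np.mean(devs))
    dev_at_mean = _deviance(
        subs, th_a.mean(axis=(0, 1)), th_v.mean(axis=(0, 1)), t_s.mean(axis=(0, 1))
    )
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------


@dataclass
class PPCResult:
    """Signed-RT quantiles (error trials negative, correct positive) of the
    observed data and of each posterior-predictive simulation."""

    quantile_levels: np.ndarray
    observed: np.ndarray            # (n_q,)
    simulated: np.ndarray           # (n_sim, n_q)

    @property
    def n_sim(self) -> int:
        return self.simulated.shape[0]

    def coverage(self) -> float:
        """Fraction of quantile points inside the simulated envelope."""
        lo = self.simulated.min(axis=0)
        hi = self.simulated.max(axis=0)
        return float(np.mean((self.observed >= lo) & (self.observed <= hi)))


def _signed_rts(rts: np.ndarray, correct: np.ndarray) -> np.ndarray:
    return np.where(correct, rts, -rts)


def posterior_predictive(
    samples: PosteriorSamples, trials_by_subject: dict, n_sim: int = 50,
    seed: int = 0, quantile_levels: np.ndarray | None = None, dt: float = 1e-3,
) -> PPCResult:
    """Simulate ``n_sim`` datasets from random posterior draws and summarize
    observed vs simulated group-level signed-RT quantiles."""
    if quantile_levels is None:
        quantile_levels = np.arange(0.05, 0.96, 0.05)
    include_freq = "update_freq" in samples.coef_names
    coef_cells = [c for c in samples.coef_names if c not in ("intercept", "update_freq")]
    subs = [_Subject(trials_by_subject[sid], coef_cells, include_freq)
            for sid in samples.subject_ids]

    obs_rts, obs_ok = [], []
    for sid in samples.subject_ids:
        for _, _, r, u in _grouped_trials(trials_by_subject[sid]):
            obs_rts.append(r)
            obs_ok.append(u)
    observed = np.quantile(_signed_rts(np.concatenate(obs_rts), np.concatenate(obs_ok)),
                           quantile_levels)

    rng = np.random.default_rng(seed)
    C, N = samples.subject["t"].shape[:2]
    sims = np.empty((n_sim, len(quantile_levels)))
    for k in range(n_sim):
        c, i = rng.integers(C), rng.integers(N)
        sim_rts, sim_ok = [], []
        for s, sub in enumerate(subs):
            a = np.exp(sub.G @ samples.subject["theta_a"][c, i, s])
            v = sub.G @ samples.subject["theta_v"][c, i, s]
            t0 = samples.subject["t"][c, i, s]
            for g in range(len(sub.rts)):
                params = DDMParams(a=float(a[g]), v=float(v[g]), t=float(max(t0, 0.0)))
                sam = simulate(params, len(sub.rts[g]), dt=dt,
                               seed=int(rng.integers(2**31 - 1)))
                good = sam["choice"] != "omission"
                sim_rts.append(sam.loc[good, "rt"].to_numpy())
                sim_ok.append((sam.loc[good, "choice"] == "upper").to_numpy())
        sims[k] = np.quantile(_signed_rts(np.concatenate(sim_rts), np.concatenate(sim_ok)),
                              quantile_levels)
    return PPCResult(quantile_levels=quantile_levels, observed=observed, simulated=sims)
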