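"""Mass-univariate single-trial EEG regression and cluster-mass inference.

Per subject, every electrode-time point of the (z-scored, decimated) epochs
is regressed on a small trial-level design using robust iteratively
reweighted least squares (bisquare weights).  Group inference is a
one-sample t across subjects on the per-subject weight maps; family-wise
error over the electrode x time grid is controlled by cluster-mass
permutation: suprathreshold points (two-sided p = 0.001 by default) are
clustered under spatiotemporal adjacency, each cluster scored by the sum of
its t-values, and the observed masses compared with the 95th percentile of
the maximum absolute cluster mass over random subject-level sign flips.

Two standard designs are provided: ``gating`` (log RT, WM state, the three
gate switches, updating frequency, and the WM state x input switch
interaction — 7 regressors) and ``representation`` (log RT, WM state,
stimulus category, action — 4 regressors).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eegsim import EpochTensor, _trial_covariate
from .montage import Montage
from .task import TrialSequence

__all__ = [
    "GLMDesign",
    "make_design",
    "BetaMaps",
    "fit_subject_glm",
    "group_tmap",
    "TMask",
    "ClusterResult",
    "cluster_mass_correct",
    "BISQUARE_C",
]

BISQUARE_C = 4.685  # standard 95%-efficiency tuning constant

_DESIGNS = {
    "gating": [
        ("log_rt", "log_rt"),
        ("wm_state", "wm_state==updating"),
        ("input_switch", "input_switch"),
        ("output_switch", "output_switch"),
        ("response_switch", "response_switch"),
        ("update_freq", "update_frequency_phase==frequent"),
        ("state_x_input", "wm_state==updating & input_switch"),
    ],
    "representation": [
        ("log_rt", "log_rt"),
        ("wm_state", "wm_state==updating"),
        ("category", "category==symbol"),
        ("action", "correct_response==different"),
    ],
}


@dataclass
class GLMDesign:
    """Named trial-level regressors (no intercept column; the fit adds it)."""

    name: str
    matrix: pd.DataFrame  # index = trial index, columns = regressor names

    @property
    def regressors(self) -> list[str]:
        return list(self.matrix.columns)


def make_design(trials: TrialSequence, kind: str = "gating",
                extra: dict[str, str] | None = None) -> GLMDesign:
    """Build the ``gating`` or ``representation`` design from labeled trials.

    Rows cover labeled, non-excluded trials; contrasts are dummy coded 1/0
    and the WM state x input switch interaction is the product of its dummy
    columns.  ``extra`` appends covariates by the same key syntax.
    """
    if kind not in _DESIGNS:
        raise ValueError(f"unknown design {kind!r}; choose from {sorted(_DESIGNS)}")
    t = trials.table
    keep = t["input_switch"].notna() & t["output_switch"].notna() & t["response_switch"].notna()
    keep &= t["correct_response"].notna()
    if "excluded" in t.columns:
        keep &= ~t["excluded"]
    sub = t.loc[keep]
    cols = {}
    spec = list(_DESIGNS[kind]) + list((extra or {}).items())
    for name, key in spec:
        cols[name] = _trial_covariate(sub, key)
    return GLMDesign(name=kind, matrix=pd.DataFrame(cols, index=sub.index))


@dataclass
class BetaMaps:
    """Per-subject regression weights: regressor x electrode x time."""

    subject: object
    betas: np.ndarray               # (n_regressors(+1), n_ch, n_times)
    regressors: list[str]           # includes "intercept" first
    times_ms: np.ndarray | None = None
    ch_names: list[str] | None = None

    def get(self, regressor: str) -> np.ndarray:
        return self.betas[self.regressors.index(regressor)]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def fit_subject_glm(epochs: EpochTensor, design: GLMDesign, subject=0,
                    max_iter: int = 30, tol: float = 1e-8) -> BetaMaps:
    """Robust (bisquare IRLS) regression at every electrode-time point.

    Epoch trials are aligned to the design rows through ``trial_index``;
    trials outside the design (excluded or unlabeled) are dropped.
    """
    pos = {tr: i for i, tr in enumerate(epochs.trial_index)}
    try:
        rows = np.array([pos[tr] for tr in design.matrix.index])
    except KeyError as e:
        raise ValueError(f"design trial {e} missing from epochs") from None
    Y = epochs.data[rows].reshape(len(rows), -1)  # (n, P)
    names = ["intercept"] + design.regressors
    X = np.column_stack([np.ones(len(rows)), design.matrix.to_numpy(dtype=float)])
    _check_rank(X, names)
    n, k = X.shape

    beta = np.linalg.lstsq(X, Y, rcond=None)[0]  # (k, P) OLS start
    for _ in range(max_iter):
        resid = Y - X @ beta
        s = np.median(np.abs(resid - np.median(resid, axis=0)), axis=0) / 0.6745
        # guard against (numerically) perfect fits: a collapsed scale would
        # turn rounding error into "outliers"
        floor = 1e-10 * np.maximum(np.abs(Y).max(axis=0), 1.0)
        s = np.where(s <= floor, np.inf, s)
        u = resid / (BISQUARE_C * s)
        W = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)  # (n, P)
        A = np.einsum("ni,np,nj->pij", X, W, X)
        b = np.einsum("ni,np->pi", X, W * Y)
        new = np.linalg.solve(A + 1e-12 * np.eye(k), b[:, :, None])[:, :, 0].T  # (k, P)
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol * (1 + np.max(np.abs(beta))):
            break
    shape = (k,) + epochs.data.shape[1:]
    return BetaMaps(subject=subject, betas=beta.reshape(shape), regressors=names,
                    times_ms=epochs.times_ms.copy(), ch_names=list(epochs.ch_names))


def _stack(betas: list[BetaMaps], regressor: str) -> np.ndarray:
    return np.stack([b.get(regressor) for b in betas])  # (S, C, T)


def group_tmap(betas: list[BetaMaps], regressor: str) -> np.ndarray:
    """One-sample t across subjects at every electrode-time point.

    Points with zero between-subject variance are returned as NaN (with a
    warning) rather than +/-inf.
    """
    if len(betas) < 2:
        raise ValueError("group t-map needs at least 2 subjects")
    B = _stack(betas, regressor)
    S = B.shape[0]
    mean = B.mean(0)
    sd = B.std(0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"group_tmap: {int(degenerate.sum())} zero-variance point(s) set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
    t[degenerate] = np.nan
    return t


@dataclass
class TMask:
    """t-values retained at permutation-significant clusters (0 elsewhere)."""

    tvals: np.ndarray               # (n_ch, n_times)
    times_ms: np.ndarray
    ch_names: list[str]
    clusters: list[dict] = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        return self.tvals != 0

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("tvals", data=self.tvals)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset("channels", data=np.array(self.ch_names, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "TMask":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(tvals=f["tvals"][()], times_ms=f["time_ms"][()],
                       ch_names=[c.decode() for c in f["channels"][()]])

    def summary_json(self, path) -> None:
        out = [
            {"points": [list(map(int, p)) for p in c["points"]],
             "mass": float(c["mass"]), "p": float(c["p"])}
            for c in self.clusters
        ]
        with open(path, "w") as fh:
            json.dump(out, fh)


@dataclass
class ClusterResult:
    """Observed t-map, per-cluster permutation statistics and the final mask."""

    tmap: np.ndarray
    mask: TMask
    clusters: list[dict]
    null_max_mass: np.ndarray
    threshold_mass: float
    t_crit: float


def _find_clusters(mask: np.ndarray, adjacency: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected components of suprathreshold points.

    Adjacent: same electrode at consecutive samples, neighbor electrodes at
    the same sample, and neighbor electrodes at consecutive samples.
    """
    points = set(zip(*np.nonzero(mask)))
    neigh = [np.flatnonzero(adjacency[c]) for c in range(adjacency.shape[0])]
    clusters = []
    seen: set[tuple[int, int]] = set()
    for start in sorted(points):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            c, t = stack.pop()
            comp.append((c, t))
            for dt in (-1, 0, 1):
                tt = t + dt
                if dt != 0 and (c, tt) in points and (c, tt) not in seen:
                    seen.add((c, tt))
                    stack.append((c, tt))
                for cc in neigh[c]:
                    if (cc, tt) in points and (cc, tt) not in seen:
                        seen.add((cc, tt))
                        stack.append((cc, tt))
        clusters.append(comp)
    return clusters


def _max_cluster_mass(t: np.ndarray, t_crit: float, adjacency: np.ndarray) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        m = np.nan_to_num(sign * t) > t_crit
        if not m.any():
            continue
        for comp in _find_clusters(m, adjacency):
            mass = abs(float(sum(t[p] for p in comp)))
            best = max(best, mass)
    return best


def cluster_mass_correct(
    betas: list[BetaMaps], regressor: str, montage: Montage,
    alpha_form: float = 0.001, n_perm: int = 1000, seed: int = 0,
    cluster_alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-mass permutation correction of the group t-map.

    The null distribution is the maximum absolute cluster mass under random
    subject-level sign flips of the weight maps (the exchangeable null for
    a one-sample test against 0); positive and negative clusters are formed
    separately and both compete against the same max-|mass| null, so the
    family-wise error rate is controlled across both signs.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: the null percentile is unstable")
    B = _stack(betas, regressor)
    S, C, T = B.shape
    adjacency = montage.adjacency
    if adjacency.shape[0] != C:
        raise ValueError("montage does not match beta maps")
    t_crit = float(stats.t.ppf(1 - alpha_form / 2, S - 1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_obs = group_tmap(betas, regressor)

    # vectorized sign-flip t-maps: Sum b_i^2 is flip-invariant
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    flat = B.reshape(S, -1)
    ss = (flat**2).sum(0)
    mean_p = (signs @ flat) / S
    var_p = np.maximum(ss - S * mean_p**2, 0.0) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_p / np.sqrt(var_p / S)
    t_perm = t_perm.reshape(n_perm, C, T)

    null = np.array([_max_cluster_mass(t_perm[i], t_crit, adjacency)
                     for i in range(n_perm)])
    thresh = float(np.percentile(null, 100 * (1 - cluster_alpha)))

    clusters = []
    tv = np.zeros_like(t_obs)
    for sign in (1.0, -1.0):
        m = np.nan_to_num(sign * t_obs) > t_crit
        if not m.any():
            continue
        for comp in _find_clusters(m, adjacency):
            mass = float(sum(t_obs[p] for p in comp))
            p_val = float((1 + np.sum(null >= abs(mass))) / (1 + n_perm))
            if abs(mass) > thresh:
                clusters.append({"points": comp, "mass": mass, "p": p_val})
                for pt in comp:
                    tv[pt] = t_obs[pt]
    mask = TMask(tvals=tv, times_ms=betas[0].times_ms, ch_names=betas[0].ch_names,
                 clusters=clusters)
    return ClusterResult(tmap=t_obs, mask=mask, clusters=clusters,
                         null_max_mass=null, threshold_mass=thresh, t_crit=t_crit)
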