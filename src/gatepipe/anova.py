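"""Repeated-measures ANOVA on condition-cell means.

Behavioral effects of gate switching are assessed with classical
fully-crossed within-subject ANOVA on per-subject cell means of RT
(correct, retained trials) and error rate (retained trials): each effect's
F is MS_effect / MS_(effect x subject), and partial eta-squared is
SS_effect / (SS_effect + SS_error).  Any fully-crossed within design is
accepted, so the three-way gate-switch analysis and larger crossings run
through the same engine.

The partition is computed directly from marginal means (inclusion-
exclusion), which keeps degenerate designs well-defined: a factor with no
variance at all yields F = 0 rather than a 0/0 artifact.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .task import TrialSequence

__all__ = ["aggregate_cells", "rm_anova"]


def aggregate_cells(trials_by_subject: dict, factors: list[str]) -> pd.DataFrame:
    """Per-subject per-cell mean RT and error rate.

    ``factors`` are column names of the trial table (e.g. ``wm_state``,
    ``category``, ``correct_response`` or the switch labels).  Only retained
    (non-excluded) trials enter; RT means use correct trials only.  A
    missing subject x cell combination raises an error naming the cell.
    """
    frames = []
    for sid, seq in trials_by_subject.items():
        t = seq.table if isinstance(seq, TrialSequence) else seq
        if "excluded" in t.columns:
            t = t.loc[~t["excluded"]]
        t = t.dropna(subset=factors)
        g = t.groupby(factors, observed=True, dropna=False)
        rec = g.apply(
            lambda d: pd.Series(
                {
                    "mean_rt": d.loc[d["accuracy"].astype(bool), "rt"].mean(),
                    "error_rate": 1.0 - d["accuracy"].astype(bool).mean(),
                    "n_trials": len(d),
                }
            ),
            include_groups=False,
        ).reset_index()
        rec.insert(0, "subject", sid)
        frames.append(rec)
    cells = pd.concat(frames, ignore_index=True)

    levels = [sorted(cells[f].astype(str).unique()) for f in factors]
    expect = int(np.prod([len(lv) for lv in levels]))
    for sid, d in cells.groupby("subject"):
        if len(d) != expect or d["mean_rt"].isna().any():
            have = set(map(tuple, d[factors].astype(str).to_numpy()))
            missing = [c for c in product(*levels) if c not in have]
            empty = d.loc[d["mean_rt"].isna(), factors].astype(str).to_numpy().tolist()
            raise ValueError(
                f"subject {sid}: incomplete crossing; missing cells {missing}, "
                f"cells without correct trials {empty}"
            )
    return cells


def rm_anova(cells: pd.DataFrame, dv: str, factors: list[str]) -> pd.DataFrame:
    """Within-subject ANOVA table: F, dfs, p and partial eta-squared for
    every main effect and interaction of ``factors``.

    ``cells`` is the output of :func:`aggregate_cells` (one row per subject
    x cell).  The error term for each effect is its interaction with
    subjects, the classical partition for a fully-crossed design with one
    observation per cell.
    """
    cells = cells.copy()
    for f in factors:
        cells[f] = cells[f].astype(str)
    counts = cells.groupby(["subject"] + list(factors)).size()
    if (counts != 1).any():
        raise ValueError("design is not fully crossed with one row per subject x cell")
    levels = {f: sorted(cells[f].unique()) for f in factors}
    n_subj = cells["subject"].nunique()
    y = cells[dv].to_numpy(dtype=float)
    scale = float((y - y.mean()).var()) * len(y) + 1e-300

    rows = []
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            # inclusion-exclusion estimates of the effect, with and without
            # the subject factor
            est = np.zeros(len(cells))
            est_s = np.zeros(len(cells))
            for k in range(len(combo) + 1):
                for sub in combinations(combo, k):
                    sign = (-1) ** (len(combo) - len(sub))
                    m = (cells.groupby(list(sub))[dv].transform("mean")
                         if sub else cells[dv].mean())
                    est = est + sign * m
                    est_s = est_s + sign * cells.groupby(list(sub) + ["subject"])[dv].transform("mean")
            ss_e = float((est**2).sum())
            ss_err = float(((est_s - est) ** 2).sum())
            df1 = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df2 = df1 * (n_subj - 1)
            if ss_e <= 1e-14 * scale:
                F, p, eta = 0.0, 1.0, 0.0
            elif ss_err <= 1e-14 * scale:
                F, p, eta = np.inf, 0.0, 1.0
            else:
                F = (ss_e / df1) / (ss_err / df2)
                p = float(f_dist.sf(F, df1, df2))
                eta = ss_e / (ss_e + ss_err)
            rows.append(dict(effect=" x ".join(combo), F=F, df1=df1, df2=df2,
                             p=p, partial_eta_sq=eta))
    return pd.DataFrame(rows)
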