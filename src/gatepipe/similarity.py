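"""Trial-by-trial similarity indexing of prioritized representations.

A trial's similarity to a representation is the dot product between its
electrode x time voltage map and the GLM t-mask of that representation
(category or action), read out in sliding 40 ms windows (8 ms step at
125 Hz: 121 windows per 125-sample epoch) restricted to windows where the
mask is significant.  Because the mask points carry the sign of the coded
level's effect, the difference in mean similarity between trials probing
the coded level and trials probing the other level is a discrimination
index already signed into the mask's preferred direction; the gating
question is whether that index grows on gate-switch trials relative to
repeats.  Trials whose stimulus token repeats from the previous trial are
excluded first, so output-repeat trials always involve a perceptual change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eegsim import EpochTensor
from .glm import TMask
from .task import TrialSequence

__all__ = [
    "SimilaritySeries",
    "trial_similarity",
    "sliding_similarity",
    "exclude_stimulus_repeats",
    "switch_repeat_contrast",
]

_REP_COLUMN = {"category": ("category", "symbol"), "action": ("correct_response", "different")}
_GATE_COLUMN = {"output": "output_switch", "response": "response_switch"}


def _check_axes(epochs: EpochTensor, mask: TMask) -> None:
    if list(epochs.ch_names) != list(mask.ch_names):
        raise ValueError("epochs and mask have different channel sets")
    if len(epochs.times_ms) != len(mask.times_ms) or not np.allclose(
        epochs.times_ms, mask.times_ms
    ):
        raise ValueError("epochs and mask have different time axes")


def trial_similarity(epochs: EpochTensor, mask: TMask) -> np.ndarray:
    """Whole-epoch similarity per trial: sum over mask points of
    (trial voltage x mask t-value)."""
    _check_axes(epochs, mask)
    return np.einsum("nct,ct->n", epochs.data, mask.tvals)


@dataclass
class SimilaritySeries:
    """Per-trial similarity at sliding-window centers.

    ``values`` is (trials, windows) in µV·t units; ``valid`` marks windows
    containing at least one mask point (values elsewhere are NaN).
    """

    values: np.ndarray
    centers_ms: np.ndarray
    valid: np.ndarray
    trial_index: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long trial x window table for CSV export."""
        n, w = self.values.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(self.trial_index, w),
                "center_ms": np.tile(self.centers_ms, n),
                "valid": np.tile(self.valid, n),
                "similarity": self.values.ravel(),
            }
        )


def sliding_similarity(epochs: EpochTensor, mask: TMask, window_ms: float = 40.0,
                       step_ms: float = 8.0, normalize: bool = False) -> SimilaritySeries:
    """Similarity in sliding time bins across the epoch.

    Window and step are rounded to whole samples (5 and 1 at 125 Hz, giving
    121 windows over a 125-sample epoch).  ``normalize=True`` divides each
    window by its mask-point count; off by default since windows are
    compared within, not across, positions.
    """
    _check_axes(epochs, mask)
    dt = float(np.median(np.diff(epochs.times_ms)))
    win = int(round(window_ms / dt))
    step = int(round(step_ms / dt))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if step < 1:
        raise ValueError("step shorter than one sample")
    n_t = len(epochs.times_ms)
    starts = np.arange(0, n_t - win + 1, step)
    centers = epochs.times_ms[starts] + (win - 1) * dt / 2.0

    n = epochs.n_trials
    values = np.full((n, len(starts)), np.nan)
    valid = np.zeros(len(starts), dtype=bool)
    support = mask.tvals != 0
    for w, s in enumerate(starts):
        sl = slice(s, s + win)
        if not support[:, sl].any():
            continue
        valid[w] = True
        values[:, w] = np.einsum("nct,ct->n", epochs.data[:, :, sl], mask.tvals[:, sl])
        if normalize:
            values[:, w] /= support[:, sl].sum()
    return SimilaritySeries(values=values, centers_ms=centers, valid=valid,
                            trial_index=epochs.trial_index.copy())


def exclude_stimulus_repeats(trials: TrialSequence) -> TrialSequence:
    """Flag trials whose stimulus token equals the previous trial's token.

    Category repeats with a token change (e.g. "X" then "O") are retained,
    so gate-repeat trials in the contrast always involve a perceptual
    change.
    """
    t = trials.table.copy()
    t["stimulus_repeat"] = t["stimulus"].eq(t["stimulus"].shift(1)).fillna(False)
    return TrialSequence(table=t, config=trials.config)


def _window_index(sim: SimilaritySeries, rep_mask_1, rep_mask_0,
                  rows: np.ndarray, w: int) -> float | None:
    v = sim.values[rows, w]
    g1 = v[rep_mask_1[rows]]
    g0 = v[rep_mask_0[rows]]
    if len(g1) < 2 or len(g0) < 2:
        return None
    return float(g1.mean() - g0.mean())


def switch_repeat_contrast(
    series, trials, gate: str, representation: str,
    mode: str = "paired", alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window test of whether representation discrimination is larger on
    gate-switch than gate-repeat trials.

    ``series``/``trials`` are single objects or parallel lists (one per
    subject).  ``mode="paired"`` (default) computes each subject's
    switch-minus-repeat discrimination index per window and runs a paired
    (one-sample) t across subjects; ``mode="pooled"`` runs a two-sample t
    across trials on the rep-signed similarity.  Windows are marked
    significant at p < ``alpha``; windows without the mask or with fewer
    than 2 trials in any cell come back indeterminate (NaN statistics).
    """
    if gate not in _GATE_COLUMN:
        raise ValueError(f"gate must be one of {sorted(_GATE_COLUMN)}")
    if representation not in _REP_COLUMN:
        raise ValueError(f"representation must be one of {sorted(_REP_COLUMN)}")
    if not isinstance(series, (list, tuple)):
        series, trials = [series], [trials]
    if mode == "paired" and len(series) < 2:
        raise ValueError("paired mode needs >= 2 subjects; use mode='pooled'")

    gate_col = _GATE_COLUMN[gate]
    rep_col, rep_coded = _REP_COLUMN[representation]

    prepared = []
    for sim, seq in zip(series, trials):
        seq = exclude_stimulus_repeats(seq)
        t = seq.table.loc[sim.trial_index]
        keep = (
            t[gate_col].notna()
            & t[rep_col].notna()
            & ~t["stimulus_repeat"]
            & (~t["excluded"] if "excluded" in t.columns else True)
        ).to_numpy(dtype=bool)
        rep1 = (t[rep_col].astype(str) == rep_coded).to_numpy() & keep
        rep0 = (t[rep_col].astype(str) != rep_coded).to_numpy() & keep
        sw = t[gate_col].fillna(False).to_numpy(dtype=bool)
        prepared.append((sim, rep1, rep0, sw & keep, ~sw & keep))

    n_w = series[0].n_windows
    valid_all = np.all([s.valid for s in series], axis=0)
    rows = []
    for w in range(n_w):
        rec = dict(center_ms=float(series[0].centers_ms[w]), valid=bool(valid_all[w]),
                   index_switch=np.nan, index_repeat=np.nan, t=np.nan, p=np.nan,
                   significant=False)
        if valid_all[w]:
            if mode == "paired":
                diffs, i_sw, i_rp = [], [], []
                for sim, rep1, rep0, sw_rows, rp_rows in prepared:
                    d_sw = _window_index(sim, rep1, rep0, sw_rows, w)
                    d_rp = _window_index(sim, rep1, rep0, rp_rows, w)
                    if d_sw is None or d_rp is None:
                        continue
                    diffs.append(d_sw - d_rp)
                    i_sw.append(d_sw)
                    i_rp.append(d_rp)
                if len(diffs) >= 2:
                    tt, pp = stats.ttest_1samp(diffs, 0.0)
                    rec.update(index_switch=float(np.mean(i_sw)),
                               index_repeat=float(np.mean(i_rp)),
                               t=float(tt), p=float(pp), significant=bool(pp < alpha))
            elif mode == "pooled":
                sw_vals, rp_vals = [], []
                for sim, rep1, rep0, sw_rows, rp_rows in prepared:
                    signed = np.where(rep1, 1.0, -1.0) * sim.values[:, w]
                    sw_vals.append(signed[sw_rows & (rep1 | rep0)])
                    rp_vals.append(signed[rp_rows & (rep1 | rep0)])
                sw_vals = np.concatenate(sw_vals)
                rp_vals = np.concatenate(rp_vals)
                if len(sw_vals) >= 2 and len(rp_vals) >= 2:
                    tt, pp = stats.ttest_ind(sw_vals, rp_vals)
                    rec.update(index_switch=float(sw_vals.mean()),
                               index_repeat=float(rp_vals.mean()),
                               t=float(tt), p=float(pp), significant=bool(pp < alpha))
            else:
                raise ValueError("mode must be 'paired' or 'pooled'")
        rows.append(rec)
    return pd.DataFrame(rows)
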