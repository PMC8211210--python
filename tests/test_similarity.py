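"""Mask-similarity indexing: dot products, sliding windows, gating contrast."""

import numpy as np
import pandas as pd
import pytest

from gatepipe import (
    ComponentSpec,
    NoiseConfig,
    TaskConfig,
    TrialSequence,
    exclude_stimulus_repeats,
    generate_epochs,
    sliding_similarity,
    switch_repeat_contrast,
    trial_similarity,
)
from gatepipe.eegsim import EpochTensor
from gatepipe.glm import TMask

from conftest import grid_montage


@pytest.fixture(scope="module")
def montage16():
    return grid_montage(4, 4)


def epochs_125(data, montage):
    times = np.arange(-200.0, 800.0, 8.0)
    assert data.shape[2] == 125
    return EpochTensor(data=data, times_ms=times, ch_names=montage.ch_names,
                       montage=montage)


def mask_patch(montage, tvals_patch, chans, tslice):
    times = np.arange(-200.0, 800.0, 8.0)
    tv = np.zeros((montage.n_channels, 125))
    tv[np.ix_(chans, range(*tslice.indices(125)))] = tvals_patch
    return TMask(tvals=tv, times_ms=times, ch_names=montage.ch_names)


def prioritization_trials(rng, n=150):
    """Labeled maintenance trials with random category and output switch."""
    t = pd.DataFrame({
        "block": 0, "trial_in_block": np.arange(n) + 2,
        "category": rng.choice(["letter", "symbol"], n),
        "frame_color": "blue", "wm_state": "maintenance",
        "update_frequency_phase": "rare", "exclude_flag": False,
        "correct_response": rng.choice(["same", "different"], n),
        "input_switch": False,
        "output_switch": rng.random(n) < 0.5,
        "response_switch": False,
        "undefined_reference": False, "undefined_switch": False,
        "choice": "same", "rt": rng.uniform(0.4, 1.2, n), "accuracy": True,
    })
    t["stimulus"] = np.where(
        t.category == "letter",
        np.where(np.arange(n) % 2 == 0, "X", "O"),
        np.where(np.arange(n) % 2 == 0, "%", "#"),
    )
    for c in ("input_switch", "output_switch", "response_switch"):
        t[c] = t[c].astype("boolean")
    return TrialSequence(t, TaskConfig())


class TestTrialSimilarity:
    def test_self_similarity_is_sum_of_squares(self, montage16):
        mask = mask_patch(montage16, 2.5, [3, 4, 5], slice(40, 60))
        data = np.tile(mask.tvals, (4, 1, 1))
        ep = epochs_125(data, montage16)
        got = trial_similarity(ep, mask)
        assert np.allclose(got, (mask.tvals**2).sum())

    def test_orthogonal_map_gives_zero(self, montage16):
        mask = mask_patch(montage16, 1.0, [0, 1], slice(10, 20))
        data = np.zeros((3, 16, 125))
        data[:, 5:, 30:] = 7.0  # disjoint from the mask support
        assert np.allclose(trial_similarity(epochs_125(data, montage16), mask), 0.0)

    def test_matches_bruteforce_loop(self, montage16):
        rng = np.random.default_rng(0)
        mask = mask_patch(montage16, rng.standard_normal((3, 20)), [2, 7, 9],
                          slice(50, 70))
        ep = epochs_125(rng.standard_normal((10, 16, 125)), montage16)
        got = trial_similarity(ep, mask)
        want = np.array([
            sum(ep.data[i, c, t] * mask.tvals[c, t]
                for c in range(16) for t in range(125))
            for i in range(10)
        ])
        assert np.allclose(got, want, atol=1e-10)

    def test_linearity_in_trial_map(self, montage16):
        rng = np.random.default_rng(1)
        mask = mask_patch(montage16, 1.5, [1, 2], slice(30, 50))
        X = rng.standard_normal((5, 16, 125))
        Y = rng.standard_normal((5, 16, 125))
        a, b = 2.0, -0.7
        sx = trial_similarity(epochs_125(X, montage16), mask)
        sy = trial_similarity(epochs_125(Y, montage16), mask)
        sxy = trial_similarity(epochs_125(a * X + b * Y, montage16), mask)
        assert np.allclose(sxy, a * sx + b * sy, atol=1e-9)

    def test_axis_mismatch_rejected(self, montage16):
        mask = mask_patch(montage16, 1.0, [0], slice(0, 5))
        bad = EpochTensor(data=np.zeros((2, 16, 100)),
                          times_ms=np.arange(100.0),
                          ch_names=montage16.ch_names)
        with pytest.raises(ValueError, match="time axes"):
            trial_similarity(bad, mask)


class TestSlidingSimilarity:
    def test_121_windows_at_125hz(self, montage16):
        mask = mask_patch(montage16, 1.0, [0], slice(60, 62))
        ep = epochs_125(np.zeros((2, 16, 125)), montage16)
        s = sliding_similarity(ep, mask, window_ms=40, step_ms=8)
        assert s.n_windows == 121

    def test_single_window_mask(self, montage16):
        # mask confined to one sample -> exactly the windows containing it
        mask = mask_patch(montage16, 1.0, [3], slice(60, 61))
        ep = epochs_125(np.ones((2, 16, 125)), montage16)
        s = sliding_similarity(ep, mask)
        # 5-sample windows starting at 56..60 contain sample 60
        assert s.valid.sum() == 5
        assert set(np.flatnonzero(s.valid)) == set(range(56, 61))

    def test_tiling_windows_sum_to_whole_trial(self, montage16):
        rng = np.random.default_rng(2)
        mask = mask_patch(montage16, rng.standard_normal((4, 30)), [1, 5, 8, 12],
                          slice(40, 70))
        ep = epochs_125(rng.standard_normal((6, 16, 125)), montage16)
        s = sliding_similarity(ep, mask, window_ms=40, step_ms=40)  # disjoint tiling
        whole = trial_similarity(ep, mask)
        summed = np.nansum(s.values[:, s.valid], axis=1)
        assert np.allclose(summed, whole, atol=1e-9)

    def test_window_shorter_than_sample_rejected(self, montage16):
        mask = mask_patch(montage16, 1.0, [0], slice(0, 5))
        ep = epochs_125(np.zeros((2, 16, 125)), montage16)
        with pytest.raises(ValueError, match="window"):
            sliding_similarity(ep, mask, window_ms=2)


class TestExcludeStimulusRepeats:
    @staticmethod
    def _seq(tokens):
        cats = {"X": "letter", "O": "letter", "%": "symbol", "#": "symbol"}
        t = pd.DataFrame({
            "block": 0, "trial_in_block": np.arange(len(tokens)),
            "stimulus": tokens, "category": [cats[x] for x in tokens],
        })
        return TrialSequence(t, TaskConfig())

    def test_token_repeat_excluded(self):
        out = exclude_stimulus_repeats(self._seq(["X", "X"]))
        assert out.table.stimulus_repeat.tolist() == [False, True]

    def test_category_repeat_with_token_change_retained(self):
        out = exclude_stimulus_repeats(self._seq(["X", "O"]))
        assert out.table.stimulus_repeat.tolist() == [False, False]

    def test_alternating_tokens_no_exclusions(self):
        out = exclude_stimulus_repeats(self._seq(["X", "O", "X", "O", "%", "#"]))
        assert not out.table.stimulus_repeat.any()


class TestSwitchRepeatContrast:
    @staticmethod
    def _subject_data(rng, montage, gain_switch=0.0, n=150):
        topo = np.zeros(montage.n_channels)
        topo[[5, 6, 9, 10]] = [1, -1, 1, -1]
        trials = prioritization_trials(rng, n)
        comp = ComponentSpec(
            "cat", topo, ("gaussian", 400.0, 60.0),
            modulators={"category==symbol": 1.5,
                        "category==symbol & output_switch": gain_switch},
        )
        noise = NoiseConfig(sd=4.0, spatial_scale_m=0.05, ar_coef=0.8)
        ep = generate_epochs(trials, [comp], noise=noise, rate=125.0,
                             seed=int(rng.integers(2**31 - 1)), montage=montage)
        return trials, ep

    @classmethod
    def _mask(cls, montage):
        times = np.arange(-200.0, 800.0, 8.0)
        topo = np.zeros(montage.n_channels)
        topo[[5, 6, 9, 10]] = [1, -1, 1, -1]
        tc = np.exp(-((times - 400.0) ** 2) / (2 * 60.0**2))
        tv = np.outer(topo / np.linalg.norm(topo), np.where(tc > 0.4, tc, 0)) * 3
        return TMask(tvals=tv, times_ms=times, ch_names=montage.ch_names)

    def test_planted_gain_detected(self, montage16):
        rng = np.random.default_rng(3)
        mask = self._mask(montage16)
        series, seqs = [], []
        for s in range(10):
            trials, ep = self._subject_data(rng, montage16, gain_switch=1.5)
            series.append(sliding_similarity(ep, mask))
            seqs.append(trials)
        res = switch_repeat_contrast(series, seqs, gate="output",
                                     representation="category")
        marked = res[res.significant]
        assert len(marked) > 0
        # all marked windows lie inside the planted support
        support_t = mask.times_ms[np.any(mask.tvals != 0, axis=0)]
        lo, hi = support_t.min() - 40, support_t.max() + 40
        assert marked.center_ms.between(lo, hi).all()
        assert (marked.index_switch > marked.index_repeat).all()

    def test_exchangeable_null_contrast_near_zero(self, montage16):
        # switch and repeat trials drawn from the identical generator
        rng = np.random.default_rng(4)
        mask = self._mask(montage16)
        series, seqs = [], []
        for s in range(10):
            trials, ep = self._subject_data(rng, montage16, gain_switch=0.0)
            series.append(sliding_similarity(ep, mask))
            seqs.append(trials)
        res = switch_repeat_contrast(series, seqs, gate="output",
                                     representation="category")
        valid = res[res.valid]
        # the paired t statistic is the group-mean contrast divided by its
        # across-subject SE: within 2 SE of 0 at the center of the support
        mid = valid.iloc[(valid.center_ms - 400).abs().argsort()[:5]]
        assert np.abs(mid.t).max() < 2.0

    def test_no_bias_without_representation_signal(self, montage16):
        # mask applied to data with no category code: discrimination ~ 0
        rng = np.random.default_rng(5)
        mask = self._mask(montage16)
        series, seqs = [], []
        for s in range(8):
            trials = prioritization_trials(rng, 120)
            ep = generate_epochs(trials, [], noise=NoiseConfig(sd=4.0),
                                 rate=125.0, seed=int(rng.integers(2**31 - 1)),
                                 montage=montage16)
            series.append(sliding_similarity(ep, mask))
            seqs.append(trials)
        res = switch_repeat_contrast(series, seqs, gate="output",
                                     representation="category")
        frac = res.loc[res.valid, "significant"].mean()
        assert frac <= 0.2

    def test_pooled_mode_single_subject(self, montage16):
        rng = np.random.default_rng(6)
        mask = self._mask(montage16)
        trials, ep = self._subject_data(rng, montage16, gain_switch=2.0, n=300)
        series = sliding_similarity(ep, mask)
        res = switch_repeat_contrast(series, trials, gate="output",
                                     representation="category", mode="pooled")
        assert res.significant.any()

    def test_paired_mode_requires_multiple_subjects(self, montage16):
        rng = np.random.default_rng(7)
        mask = self._mask(montage16)
        trials, ep = self._subject_data(rng, montage16)
        series = sliding_similarity(ep, mask)
        with pytest.raises(ValueError, match="pooled"):
            switch_repeat_contrast(series, trials, gate="output",
                                   representation="category", mode="paired")
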