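"""Reference-back-2 task engine.

The reference-back-2 task is a continuous working-memory (WM) updating task.
On every trial one stimulus from one of two categories (letters ``X``/``O``,
symbols ``%``/``#``) appears inside a colored frame.  One frame color marks an
*updating* trial (the probed category's memory slot is rewritten with the
stimulus), the other a *maintenance* trial (memory is untouched).  Regardless
of frame color the participant decides whether the stimulus matches the item
of its own category held in memory, i.e. the last stimulus of that category
shown inside the updating color.

The engine generates trial sequences, replays the task rule to derive memory
state and correct responses, and labels the three orthogonal gate-switch
factors (input, output, response) used by every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialSequence",
    "generate_session",
    "label_trials",
    "apply_exclusions",
    "RT_FLOOR_S",
    "RT_CEILING_S",
]

#: Trials faster than this (strictly) are discarded as anticipations.
RT_FLOOR_S = 0.200
#: Responses are only collected up to this deadline.
RT_CEILING_S = 3.0


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a reference-back-2 session.

    Defaults follow the standard protocol: 12 blocks of 90 trials, frame
    color biased 75/25 within each half of the session with the bias
    flipping at the midpoint, two categories of two stimulus tokens each.
    """

    n_blocks: int = 12
    trials_per_block: int = 90
    bias_high: float = 0.75
    categories: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"letter": ("X", "O"), "symbol": ("%", "#")}
    )
    updating_color: str = "red"
    maintenance_color: str = "blue"
    response_mapping: dict[str, str] = field(
        default_factory=lambda: {"same": "right", "different": "left"}
    )

    def __post_init__(self) -> None:
        if self.n_blocks < 2 or self.n_blocks % 2:
            raise ValueError("n_blocks must be even (the color bias flips at the midpoint)")
        if self.trials_per_block < 2:
            raise ValueError("trials_per_block must be >= 2 (block-initial updating pair)")
        if not 0.5 <= self.bias_high <= 1.0:
            raise ValueError(f"bias_high must lie in [0.5, 1], got {self.bias_high}")
        if len(self.categories) != 2 or any(len(v) != 2 for v in self.categories.values()):
            raise ValueError("exactly 2 categories with 2 stimulus tokens each are required")
        if self.updating_color == self.maintenance_color:
            raise ValueError("updating and maintenance colors must differ")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_json(self, path) -> None:
        d = asdict(self)
        d["categories"] = {k: list(v) for k, v in d["categories"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TaskConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["categories"] = {k: tuple(v) for k, v in d["categories"].items()}
        return cls(**d)


@dataclass
class TrialSequence:
    """An ordered session of trials plus the configuration that produced it.

    ``table`` has one row per trial.  Columns added as the pipeline advances:

    generation
        block, trial_in_block, stimulus, category, frame_color, wm_state
        (``updating``/``maintenance``), update_frequency_phase
        (``frequent``/``rare``), exclude_flag (block-initial pair)
    labelling (:func:`label_trials`)
        memory_<category> slots *after* the trial, correct_response,
        input_switch / output_switch / response_switch (nullable booleans;
        NA on the session's first trial), undefined_reference,
        undefined_switch
    behavior (filled by a simulator or loaded from data)
        choice (``same``/``different``/``omission``), rt (s), accuracy
    exclusions (:func:`apply_exclusions`)
        excluded, exclude_reason
    """

    table: pd.DataFrame
    config: TaskConfig

    def __len__(self) -> int:
        return len(self.table)

    def retained(self) -> pd.DataFrame:
        """Rows surviving :func:`apply_exclusions`."""
        if "excluded" not in self.table.columns:
            raise ValueError("apply_exclusions has not been run on this sequence")
        return self.table.loc[~self.table["excluded"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: TaskConfig | None = None) -> "TrialSequence":
        table = pd.read_csv(path)
        for col in ("input_switch", "output_switch", "response_switch"):
            if col in table.columns:
                table[col] = table[col].astype("boolean")
        return cls(table=table, config=config or TaskConfig())


def generate_session(config: TaskConfig, seed: int) -> TrialSequence:
    """Draw a full session of stimuli and frame colors.

    Stimulus category and token are uniform; frame color follows the phase
    bias (``bias_high`` for the phase's frequent color, flipping between the
    first and second half of the session; which color is frequent first is
    randomized).  The first two trials of every block are forced updating
    trials covering both categories, and carry ``exclude_flag``.
    """
    rng = np.random.default_rng(seed)
    cats = list(config.categories)
    n = config.n_trials

    # which frame color dominates the first half of the session
    first_frequent = rng.choice([config.updating_color, config.maintenance_color])
    second_frequent = (
        config.maintenance_color
        if first_frequent == config.updating_color
        else config.updating_color
    )

    rows = []
    half = config.n_blocks // 2
    for b in range(config.n_blocks):
        frequent = first_frequent if b < half else second_frequent
        rare = config.maintenance_color if frequent == config.updating_color else config.updating_color
        phase = "frequent" if frequent == config.updating_color else "rare"
        cat_order = list(rng.permutation(cats))
        for i in range(config.trials_per_block):
            if i < 2:
                category = cat_order[i]
                color = config.updating_color
                forced = True
            else:
                category = cats[rng.integers(2)]
                color = frequent if rng.random() < config.bias_high else rare
                forced = False
            stimulus = config.categories[category][rng.integers(2)]
            rows.append(
                {
                    "block": b,
                    "trial_in_block": i,
                    "stimulus": stimulus,
                    "category": category,
                    "frame_color": color,
                    "wm_state": "updating" if color == config.updating_color else "maintenance",
                    "update_frequency_phase": phase,
                    "exclude_flag": forced,
                }
            )
    table = pd.DataFrame(rows)
    assert len(table) == n
    return TrialSequence(table=table, config=config)


def label_trials(seq: TrialSequence) -> TrialSequence:
    """Replay the task rule: memory state, correct response, switch labels.

    The matching decision always compares the stimulus with the memory slot
    of its own category *as held before any update on the current trial*;
    updating trials then overwrite that slot.  Switch labels relative to the
    previous trial: ``input_switch`` — WM state (updating/maintenance)
    changed; ``output_switch`` — probed category changed; ``response_switch``
    — correct response changed.  They are computed across block boundaries
    (the task is continuous); the session's first trial gets NA labels and
    ``undefined_switch``.  A probe before any reference exists in its
    category sets ``undefined_reference``.
    """
    t = seq.table.copy()
    cats = list(seq.config.categories)
    memory: dict[str, str | None] = {c: None for c in cats}

    correct, undef_ref = [], []
    mem_cols: dict[str, list] = {c: [] for c in cats}
    for stim, cat, state in zip(t["stimulus"], t["category"], t["wm_state"]):
        ref = memory[cat]
        if ref is None:
            correct.append(pd.NA)
            undef_ref.append(True)
        else:
            correct.append("same" if stim == ref else "different")
            undef_ref.append(False)
        if state == "updating":
            memory[cat] = stim
        for c in cats:
            mem_cols[c].append(memory[c])

    t["correct_response"] = correct
    t["undefined_reference"] = undef_ref
    for c in cats:
        t[f"memory_{c}"] = mem_cols[c]

    prev = t.shift(1)
    t["input_switch"] = (t["wm_state"] != prev["wm_state"]).astype("boolean")
    t["output_switch"] = (t["category"] != prev["category"]).astype("boolean")
    resp_sw = pd.array(
        [
            pd.NA if (pd.isna(a) or pd.isna(b)) else a != b
            for a, b in zip(t["correct_response"], prev["correct_response"])
        ],
        dtype="boolean",
    )
    t["response_switch"] = resp_sw
    t.loc[0, ["input_switch", "output_switch", "response_switch"]] = pd.NA
    t["undefined_switch"] = False
    t.loc[0, "undefined_switch"] = True
    return TrialSequence(table=t, config=seq.config)


def apply_exclusions(seq: TrialSequence) -> TrialSequence:
    """Flag trials the analyses must ignore, without deleting rows.

    Excluded: the first two trials of each block, omissions, anticipations
    (rt < 0.200 s, strict), and responses beyond the 3 s deadline.
    """
    t = seq.table.copy()
    reason = np.full(len(t), "", dtype=object)

    block_initial = t["exclude_flag"].to_numpy(dtype=bool)
    reason[block_initial] = "block_initial"

    if "choice" in t.columns:
        omission = t["choice"].isna().to_numpy() | (t["choice"] == "omission").to_numpy()
    else:
        omission = np.zeros(len(t), dtype=bool)
    reason[omission & (reason == "")] = "omission"

    if "rt" in t.columns:
        rt = t["rt"].to_numpy(dtype=float)
        fast = ~np.isnan(rt) & (rt < RT_FLOOR_S)
        slow = ~np.isnan(rt) & (rt > RT_CEILING_S)
    else:
        fast = slow = np.zeros(len(t), dtype=bool)
    reason[fast & (reason == "")] = "fast_rt"
    reason[slow & (reason == "")] = "slow_rt"

    t["excluded"] = block_initial | omission | fast | slow
    t["exclude_reason"] = reason
    return TrialSequence(table=t, config=seq.config)
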