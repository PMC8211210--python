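"""Shared fixtures and synthetic builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gatepipe import (
    RegressionSpec,
    TaskConfig,
    TrialSequence,
    apply_exclusions,
    generate_session,
    label_trials,
    simulate_behavior,
)
from gatepipe.fitting import REFERENCE_CELL
from gatepipe.montage import Montage, from_positions


@pytest.fixture(scope="session")
def full_session() -> TrialSequence:
    """A labeled default session: 12 blocks x 90 trials."""
    return label_trials(generate_session(TaskConfig(), seed=7))


@pytest.fixture(scope="session")
def behaving_session(full_session) -> TrialSequence:
    """Full session with DDM behavior and exclusions applied."""
    return apply_exclusions(simulate_behavior(full_session, RegressionSpec(), seed=11))


def grid_montage(nx: int, ny: int, spacing: float = 0.03) -> Montage:
    """Small rectangular montage for fast EEG tests (rook+diagonal adjacency)."""
    xy = np.array([(i, j) for i in range(nx) for j in range(ny)], dtype=float) * spacing
    pos = np.c_[xy, np.zeros(nx * ny)]
    return from_positions(
        [f"E{i}" for i in range(nx * ny)], pos, threshold=spacing * 1.5
    )


def parse_cell(name: str) -> dict:
    st, i, o, r = name.split(".")
    return dict(
        wm_state="updating" if st == "upd" else "maintenance",
        input_switch=i == "iS",
        output_switch=o == "oS",
        response_switch=r == "rS",
    )


def trials_for_cells(cells: list[str], n_per_cell: int, rng: np.random.Generator,
                     frequent: bool = False) -> TrialSequence:
    """Labeled trial table with a fixed number of trials per design cell.

    Labels are assigned directly (no task replay); stimulus tokens alternate
    so no stimulus-identity repeats occur.
    """
    rows = []
    for cell in cells:
        lab = parse_cell(cell)
        for k in range(n_per_cell):
            cat = rng.choice(["letter", "symbol"])
            rows.append(
                dict(
                    block=0,
                    trial_in_block=k + 2,
                    category=cat,
                    frame_color="red" if lab["wm_state"] == "updating" else "blue",
                    update_frequency_phase="frequent" if frequent else "rare",
                    exclude_flag=False,
                    correct_response=rng.choice(["same", "different"]),
                    undefined_reference=False,
                    undefined_switch=False,
                    **lab,
                )
            )
    t = pd.DataFrame(rows)
    t = t.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)
    tok = {"letter": ("X", "O"), "symbol": ("%", "#")}
    t["stimulus"] = [tok[c][k % 2] for k, c in enumerate(t["category"])]
    for c in ("input_switch", "output_switch", "response_switch"):
        t[c] = t[c].astype("boolean")
    return TrialSequence(table=t, config=TaskConfig())


def behaving_cells(cells, n_per_cell, spec: RegressionSpec, seed: int) -> TrialSequence:
    """trials_for_cells + DDM behavior + exclusions."""
    rng = np.random.default_rng(seed)
    seq = trials_for_cells(cells, n_per_cell, rng)
    seq = simulate_behavior(seq, spec, seed=seed + 1)
    return apply_exclusions(seq)


@pytest.fixture(scope="session")
def two_cell_subjects():
    """Eight subjects, reference cell + one response-switch cell, with a
    planted +0.3 threshold effect — shared by hierarchical-fit tests."""
    spec = RegressionSpec(a_mr=1.5, v_mr=2.0, t=0.3, a_cell={"mnt.iR.oR.rS": 0.3})
    return {
        s: behaving_cells([REFERENCE_CELL, "mnt.iR.oR.rS"], 150, spec, seed=1000 + 7 * s)
        for s in range(8)
    }, spec
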