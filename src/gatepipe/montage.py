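"""Electrode montage and spatial adjacency.

The default layout is a 62-channel subset of the extended 10-10 system
(positions taken from MNE's standard head model), matching a typical
62-electrode Ag/AgCl scalp recording.  The neighbor graph connects
electrodes closer than a distance threshold; by default the threshold is
searched so the median neighbor count lands in the 6-8 range that
spatiotemporal cluster tests conventionally use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage", "DEFAULT_62"]

DEFAULT_62 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
]


@dataclass
class Montage:
    """Electrode labels, 3-D positions (meters) and neighbor graph."""

    ch_names: list[str]
    positions: np.ndarray          # (n_ch, 3)
    adjacency: np.ndarray          # (n_ch, n_ch) boolean, symmetric, no self-edges
    threshold: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.ch_names)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be (n_channels, n_channels)")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have no self-edges")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, label: str) -> int:
        return self.ch_names.index(label)

    def distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def median_degree(self) -> float:
        return float(np.median(self.adjacency.sum(1)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ch_names": self.ch_names,
                    "positions": self.positions.tolist(),
                    "threshold": float(self.threshold),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            d = json.load(fh)
        return from_positions(d["ch_names"], np.asarray(d["positions"]),
                              threshold=d.get("threshold"))


def from_positions(ch_names, positions, threshold: float | None = None,
                   target_degree: tuple[int, int] = (6, 8)) -> Montage:
    """Build a montage from positions, picking the adjacency threshold.

    With ``threshold=None`` the smallest distance cutoff whose median
    neighbor count reaches ``target_degree[0]`` is used (capped at the
    cutoff where it would exceed ``target_degree[1]``).
    """
    positions = np.asarray(positions, dtype=float)
    d = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    if threshold is None:
        lo, hi = target_degree
        candidates = np.unique(dist[dist > 0])
        threshold = None
        for c in candidates:
            adj = (dist <= c) & ~np.eye(len(ch_names), dtype=bool)
            deg = np.median(adj.sum(1))
            if deg >= lo:
                threshold = float(c)
                if deg > hi:
                    warnings.warn(
                        f"adjacency threshold search overshot median degree {deg}"
                    )
                break
        if threshold is None:
            raise ValueError("could not find an adjacency threshold")
    adj = (dist <= threshold) & ~np.eye(len(ch_names), dtype=bool)
    return Montage(list(ch_names), positions, adj, threshold=float(threshold))


def default_montage(ch_names: list[str] | None = None) -> Montage:
    """The 62-channel 10-10 montage with auto-thresholded adjacency."""
    import mne

    ch_names = list(ch_names or DEFAULT_62)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    missing = [c for c in ch_names if c not in pos_map]
    if missing:
        raise ValueError(f"channels not in the standard 10-05 set: {missing}")
    positions = np.array([pos_map[c] for c in ch_names])
    return from_positions(ch_names, positions)
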