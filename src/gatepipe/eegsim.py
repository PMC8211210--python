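"""Synthetic epoched EEG with planted, condition-linked components.

Epochs span -200..800 ms around stimulus onset (500 Hz raw, decimated by 4
to 125 samples for analysis) and are baseline-corrected over the
prestimulus window.  Each trial's voltage is a sum of spatiotemporal
components — a fixed topography times a Gaussian-bump or boxcar time
course, with an amplitude that can be modulated by trial labels (gate
switches, category, action) and by log RT — plus spatially correlated,
temporally autocorrelated Gaussian noise.  The default component set plants
the signatures the analysis chain is meant to detect: a parietal P3b-like
positivity for input switches, a frontal N2-like negativity for output
switches, a late parietal slow-wave positivity for response switches, and
distinct category- and action-coding topographies whose gain grows on the
corresponding gate switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import decimate as _sig_decimate
from scipy.signal import lfilter

from .montage import Montage, default_montage
from .task import TrialSequence

__all__ = [
    "ComponentSpec",
    "NoiseConfig",
    "EpochTensor",
    "gaussian_topography",
    "generate_epochs",
    "decimate_epochs",
    "zscore_epochs",
    "default_components",
]

EPOCH_START_MS = -200.0
EPOCH_END_MS = 800.0


def gaussian_topography(montage: Montage, center_label: str, scale_m: float = 0.05,
                        sign: float = 1.0) -> np.ndarray:
    """Unit-normalized spatial bump centered on one electrode."""
    c = montage.positions[montage.index(center_label)]
    d2 = ((montage.positions - c) ** 2).sum(1)
    topo = sign * np.exp(-d2 / (2 * scale_m**2))
    return topo / np.linalg.norm(topo)


@dataclass
class ComponentSpec:
    """One planted spatiotemporal component.

    ``time_course``: ``("gaussian", center_ms, width_ms)`` or
    ``("boxcar", start_ms, end_ms)``; must lie inside the epoch window.
    ``modulators`` maps trial covariates to additive amplitude terms (µV):
    keys are trial-table column names, ``col==value`` indicators, the
    special key ``log_rt``, or ``&``-joined products of those.
    """

    name: str
    topography: np.ndarray
    time_course: tuple
    amplitude: float = 0.0
    modulators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        nrm = np.linalg.norm(self.topography)
        if nrm == 0:
            raise ValueError("topography must be non-zero")
        self.topography = self.topography / nrm
        kind, p1, p2 = self.time_course
        if kind == "gaussian":
            if not EPOCH_START_MS <= p1 <= EPOCH_END_MS:
                raise ValueError(f"component {self.name}: center {p1} ms outside epoch")
        elif kind == "boxcar":
            if p1 >= p2 or p1 < EPOCH_START_MS or p2 > EPOCH_END_MS:
                raise ValueError(f"component {self.name}: boxcar [{p1},{p2}] outside epoch")
        else:
            raise ValueError(f"unknown time course kind {kind!r}")

    def course(self, times_ms: np.ndarray) -> np.ndarray:
        kind, p1, p2 = self.time_course
        if kind == "gaussian":
            return np.exp(-((times_ms - p1) ** 2) / (2 * p2**2))
        return ((times_ms >= p1) & (times_ms < p2)).astype(float)


@dataclass(frozen=True)
class NoiseConfig:
    """Spatially correlated (exponential covariance over electrode
    distance), temporally AR(1) Gaussian noise."""

    sd: float = 8.0                 # µV per sample
    spatial_scale_m: float = 0.08   # e-folding distance of spatial correlation
    ar_coef: float = 0.95           # per-sample AR(1) coefficient at 500 Hz


@dataclass
class EpochTensor:
    """trials x electrodes x time voltages (µV) with time axis and montage."""

    data: np.ndarray
    times_ms: np.ndarray
    ch_names: list[str]
    montage: Montage | None = None
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, electrodes, time)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis does not match times_ms")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def rate_hz(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.times_ms)))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("voltages", data=self.data)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset("channels", data=np.array(self.ch_names, dtype="S"))
            f.create_dataset("trial_index", data=self.trial_index)

    @classmethod
    def from_hdf5(cls, path, montage: Montage | None = None) -> "EpochTensor":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["voltages"][()],
                times_ms=f["time_ms"][()],
                ch_names=[c.decode() for c in f["channels"][()]],
                montage=montage,
                trial_index=f["trial_index"][()],
            )


def _trial_covariate(table: pd.DataFrame, key: str) -> np.ndarray:
    if "&" in key:
        parts = [p.strip() for p in key.split("&")]
        out = np.ones(len(table))
        for p in parts:
            out = out * _trial_covariate(table, p)
        return out
    if key == "log_rt":
        rt = table["rt"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lr = np.log(rt)
        lr[~np.isfinite(lr)] = np.nanmean(lr[np.isfinite(lr)]) if np.isfinite(lr).any() else 0.0
        return lr
    if "==" in key:
        col, val = (p.strip() for p in key.split("=="))
        return (table[col].astype(str) == val).to_numpy(dtype=float)
    col = table[key]
    if col.dtype == "boolean":
        return col.fillna(False).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def generate_epochs(
    trials: TrialSequence,
    components: list[ComponentSpec],
    noise: NoiseConfig | None = NoiseConfig(),
    rate: float = 500.0,
    seed: int = 0,
    montage: Montage | None = None,
) -> EpochTensor:
    """Render one epoch per trial: planted components plus noise, then
    baseline correction over -200..0 ms.  Deterministic given ``seed``."""
    if montage is None:
        montage = default_montage()
    step = 1000.0 / rate
    times = np.arange(EPOCH_START_MS, EPOCH_END_MS, step)
    table = trials.table
    n, n_ch, n_t = len(table), montage.n_channels, len(times)
    data = np.zeros((n, n_ch, n_t))

    for comp in components:
        if comp.topography.shape != (n_ch,):
            raise ValueError(f"component {comp.name}: topography length != n_channels")
        amp = np.full(n, float(comp.amplitude))
        for key, delta in comp.modulators.items():
            amp = amp + delta * _trial_covariate(table, key)
        data += amp[:, None, None] * comp.topography[None, :, None] * comp.course(times)[None, None, :]

    if noise is not None:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, n_ch, n_t))
        phi = noise.ar_coef ** (500.0 / rate)  # keep correlation time in ms fixed
        z = lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], z, axis=-1)
        cov = np.exp(-montage.distances() / noise.spatial_scale_m)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(n_ch))
        data += noise.sd * np.einsum("ce,net->nct", L, z)

    base = times < 0
    data -= data[:, :, base].mean(axis=2, keepdims=True)
    return EpochTensor(data=data, times_ms=times, ch_names=list(montage.ch_names),
                       montage=montage, trial_index=table.index.to_numpy())


def decimate_epochs(epochs: EpochTensor, factor: int) -> EpochTensor:
    """Anti-alias filter and keep every ``factor``-th sample."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return EpochTensor(epochs.data.copy(), epochs.times_ms.copy(),
                           list(epochs.ch_names), epochs.montage,
                           epochs.trial_index.copy())
    data = _sig_decimate(epochs.data, factor, axis=-1, ftype="fir", zero_phase=True)
    return EpochTensor(data=data, times_ms=epochs.times_ms[::factor],
                       ch_names=list(epochs.ch_names), montage=epochs.montage,
                       trial_index=epochs.trial_index.copy())


def zscore_epochs(epochs: EpochTensor) -> EpochTensor:
    """Standardize each electrode-time point across trials."""
    if epochs.n_trials < 2:
        raise ValueError("z-scoring needs at least 2 trials")
    mu = epochs.data.mean(axis=0, keepdims=True)
    sd = epochs.data.std(axis=0, ddof=0, keepdims=True)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"zscore_epochs: {int(zero.sum())} point(s) with zero variance set to 0")
        sd = np.where(zero, 1.0, sd)
    data = (epochs.data - mu) / sd
    data[np.broadcast_to(zero, data.shape)] = 0.0
    return EpochTensor(data=data, times_ms=epochs.times_ms.copy(),
                       ch_names=list(epochs.ch_names), montage=epochs.montage,
                       trial_index=epochs.trial_index.copy())


def default_components(montage: Montage | None = None) -> list[ComponentSpec]:
    """The stock planted-effect battery mirroring the reported signatures.

    Parietal P3b-like positivity boosted by input switches, frontal N2-like
    negativity boosted by output switches, late parietal positive slow wave
    boosted by response switches, category- and action-coding topographies
    with switch-dependent gain, and a broad log-RT-coupled component giving
    the GLM's RT nuisance regressor real signal to absorb.
    """
    if montage is None:
        montage = default_montage()
    g = lambda lab, s=0.05, sign=1.0: gaussian_topography(montage, lab, s, sign)
    return [
        ComponentSpec("p3b_input", g("Pz"), ("gaussian", 420.0, 55.0),
                      amplitude=1.0, modulators={"input_switch": 3.0}),
        ComponentSpec("n2_output", g("FCz"), ("gaussian", 300.0, 45.0),
                      amplitude=-0.5, modulators={"output_switch": -2.5}),
        ComponentSpec("psw_response", g("CPz", 0.06), ("gaussian", 600.0, 80.0),
                      amplitude=0.5, modulators={"response_switch": 2.5}),
        ComponentSpec("category_code", g("PO7", 0.045) - g("PO8", 0.045),
                      ("gaussian", 400.0, 90.0), amplitude=0.0,
                      modulators={"category==symbol": 1.5,
                                  "category==symbol & output_switch": 1.0}),
        ComponentSpec("action_code", g("C3", 0.045) - g("C4", 0.045),
                      ("gaussian", 450.0, 120.0), amplitude=0.0,
                      modulators={"correct_response==different": 1.5,
                                  "correct_response==different & response_switch": 1.0}),
        ComponentSpec("rt_drift", g("Cz", 0.09), ("boxcar", 200.0, 800.0),
                      amplitude=0.0, modulators={"log_rt": 1.0}),
    ]
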