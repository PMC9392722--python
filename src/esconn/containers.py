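"""In-memory containers shared across the pipeline.

The two recording modalities are carried by :class:`TrialSet` (stimulation-locked
iEEG trial tensors) and :class:`BoldRun` (ROI-level BOLD series from block-design
stimulation runs).  Channel annotation travels as a pandas DataFrame with the
columns ``name, roi, roi_group, hemisphere, in_soz, in_white_matter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Anatomical ROI groupings used for latency and network summaries.
ROI_GROUPS = ("OF", "lPFC", "SM", "PL", "TL", "CC")

CHANNEL_COLUMNS = ("name", "roi", "roi_group", "hemisphere", "in_soz", "in_white_matter")


def _validate_channels(table: pd.DataFrame, n_channels: int) -> pd.DataFrame:
    missing = [c for c in CHANNEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    if len(table) != n_channels:
        raise ValueError(
            f"channel table has {len(table)} rows for {n_channels} recorded channels"
        )
    table = table.copy()
    # unknown ROI group labels collapse to "other"
    table["roi_group"] = [
        g if g in ROI_GROUPS else "other" for g in table["roi_group"].astype(str)
    ]
    return table.reset_index(drop=True)


@dataclass
class TrialSet:
    """Stimulation-locked multichannel trial tensor.

    Parameters
    ----------
    data
        Array of shape (channels, trials, samples), in volts (or already in
        baseline-SD units for noiseless constructions).
    fs
        Sampling rate in Hz.
    t0_index
        Sample index of stimulation onset.
    channels
        Channel annotation table (one row per channel).
    stim_group
        ``"medial"`` or ``"lateral"`` amygdala stimulation.
    """

    data: np.ndarray
    fs: float
    t0_index: int
    channels: pd.DataFrame
    stim_group: str = "medial"
    run_id: str = "run-1"
    seed: Optional[int] = None
    ground_truth: Optional[object] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, trials, samples)")
        if not (0 <= self.t0_index < self.data.shape[2]):
            raise ValueError("t0_index outside the record")
        self.channels = _validate_channels(self.channels, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulation onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs * 1e3

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Half-open window [start_ms, stop_ms) mapped with floor(fs * t)."""
        a = self.t0_index + int(np.floor(self.fs * start_ms / 1e3))
        b = self.t0_index + int(np.floor(self.fs * stop_ms / 1e3))
        return slice(max(a, 0), min(b, self.n_samples))


@dataclass
class EvokedPotential:
    """Per-channel trial-averaged response, normalized to baseline SD units."""

    trace: np.ndarray                 # (channels, samples), SD units
    fs: float
    t0_index: int
    channels: pd.DataFrame
    n_trials_used: np.ndarray         # (channels,)
    baseline_sd: np.ndarray           # (channels,), volts
    valid: np.ndarray                 # (channels,) bool — False: absent channel
    stim_group: str = "medial"
    run_id: str = "run-1"
    invalid_reason: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.trace.shape[1]) - self.t0_index) / self.fs * 1e3

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        a = self.t0_index + int(np.floor(self.fs * start_ms / 1e3))
        b = self.t0_index + int(np.floor(self.fs * stop_ms / 1e3))
        return slice(max(a, 0), min(b, self.trace.shape[1]))


@dataclass
class SpectralMatrix:
    """Cross-spectral density matrix on a uniform frequency grid up to Nyquist."""

    S: np.ndarray            # (n_freqs, channels, channels), complex
    freqs: np.ndarray        # (n_freqs,), Hz; freqs[0] == 0, freqs[-1] == Nyquist
    fs: float
    n_trials: int = 0
    n_tapers: int = 0
    window_ms: tuple = (70.0, 200.0)

    def nearest_bin(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f_hz)))


@dataclass
class FactorizationResult:
    """Minimum-phase spectral factorization S(f) = H(f) Sigma H(f)*."""

    H: np.ndarray            # (n_freqs, ch, ch), complex
    Sigma: np.ndarray        # (ch, ch), real SPD innovation covariance
    iterations: int
    residual: float
    converged: bool


@dataclass
class SpectralCGCResult:
    """Frequency-resolved conditional Granger causality with surrogate threshold."""

    cgc: np.ndarray                       # (source, target, n_freqs), >= 0, diag NaN
    freqs: np.ndarray
    channels: pd.DataFrame
    threshold: Optional[np.ndarray] = None   # (source, target) at eval frequency
    eval_freq_hz: Optional[float] = None
    eval_bin: Optional[int] = None

    @property
    def significant(self) -> Optional[np.ndarray]:
        if self.threshold is None or self.eval_bin is None:
            return None
        at = self.cgc[:, :, self.eval_bin]
        with np.errstate(invalid="ignore"):
            return at > self.threshold


@dataclass
class BoldRun:
    """ROI-level BOLD series from one block-design stimulation run."""

    series: np.ndarray            # (n_roi, n_frames)
    roi_names: list
    tr: float                     # seconds
    onsets: np.ndarray            # block onset frame indices (start of ON)
    frames_on: int
    frames_off: int
    fd: np.ndarray                # (n_frames,), mm
    stim_group: str = "medial"
    run_id: str = "run-1"
    seed: Optional[int] = None
    ground_truth: Optional[object] = None
    betas: Optional[np.ndarray] = None      # (n_roi, n_basis)
    residuals: Optional[np.ndarray] = None  # (n_roi, n_frames)
    censor_mask: Optional[np.ndarray] = None  # True = frame usable

    @property
    def n_roi(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]


@dataclass
class PartialCorrNetwork:
    """Fisher-z partial-correlation network for one run and condition."""

    z: np.ndarray            # (n_roi, n_roi), symmetric, zero diagonal
    roi_names: list
    condition: str           # "ON" | "OFF" | "all"
    run_id: str = "run-1"
    stim_group: str = "medial"
    n_frames_used: int = 0
    membership: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("partial-correlation matrix must be symmetric")
        np.fill_diagonal(self.z, 0.0)
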