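"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's inputs:

* :func:`simulate_ep_trials` — stimulation-locked iEEG trials with two evoked
  components (an early ~15 ms deflection of either polarity and a late ~150 ms
  positive deflection) whose latency and amplitude depend on the anatomical
  ROI group and on the stimulated amygdala subdivision (medial vs lateral),
  riding on 1/f background noise with occasional artifact trials.
* :func:`simulate_var` — stationary vector-autoregressive trial segments with
  known directed coupling, the validation oracle for spectral Granger
  causality (the analytic spectrum and time-domain Geweke values are
  computable from the coefficients).
* :func:`simulate_bold` — ROI-level block-design BOLD runs: block regressor
  convolved with a double-gamma hemodynamic kernel, plus correlated Gaussian
  noise drawn from a ground-truth precision matrix, plus motion spikes
  mirrored in the frame-wise-displacement trace.

All randomness flows through one ``numpy.random.Generator`` derived from the
``seed`` argument; the seed is recorded on every returned container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ROI_GROUPS, BoldRun, TrialSet
from .splines import cardinal_spline_basis

EARLY_WINDOW_MS = (10.0, 30.0)
LATE_WINDOW_MS = (70.0, 200.0)


# ---------------------------------------------------------------------------
# evoked-potential ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroupResponse:
    """Evoked-response parameters for one (roi_group, stim_group) cell."""

    early_latency_ms: float
    early_amplitude_sd: float      # signed: sign sets N vs P polarity
    late_latency_ms: float
    late_amplitude_sd: float       # late component is defined positive
    noise_exponent: float = 1.0    # 1/f^alpha background slope
    artifact_rate: float = 0.0     # fraction of trials carrying an artifact

    def __post_init__(self) -> None:
        if not (EARLY_WINDOW_MS[0] <= self.early_latency_ms < EARLY_WINDOW_MS[1]):
            raise ValueError("early latency outside the early analysis window")
        if not (LATE_WINDOW_MS[0] <= self.late_latency_ms < LATE_WINDOW_MS[1]):
            raise ValueError("late latency outside the late analysis window")
        if self.late_amplitude_sd < 0:
            raise ValueError("late amplitude must be non-negative")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be a fraction")


@dataclass
class EpGroundTruth:
    """Per-(roi_group, stim_group) evoked-response ground truth.

    ``entries`` maps ``(roi_group, stim_group)`` to :class:`GroupResponse`.
    Component widths are Gaussian sigmas in ms.
    """

    entries: Dict[Tuple[str, str], GroupResponse]
    early_width_ms: float = 4.0
    late_width_ms: float = 40.0

    def response(self, roi_group: str, stim_group: str) -> GroupResponse:
        return self.entries[(roi_group, stim_group)]


#: Group-mean latencies emulating the propagation order seen in human CCEPs:
#: orbitofrontal and cingulate respond first, parietal cortex last, for both
#: components.
_DEFAULT_EARLY_LAT = {"OF": 17.0, "CC": 16.6, "lPFC": 18.0, "TL": 18.5,
                      "SM": 19.5, "PL": 20.8}
_DEFAULT_LATE_LAT = {"OF": 129.0, "CC": 143.3, "lPFC": 147.0, "SM": 155.0,
                     "PL": 157.0, "TL": 157.0}
#: Early (N15-like) responses are negative-going in frontal groups and
#: positive elsewhere; lateral stimulation drives larger early amplitudes,
#: medial stimulation larger late amplitudes.
_EARLY_SIGN = {"OF": -1.0, "CC": -1.0, "lPFC": -1.0, "TL": 1.0, "SM": 1.0, "PL": 1.0}


def default_ep_ground_truth(artifact_rate: float = 0.05,
                            noise_exponent: float = 1.0) -> EpGroundTruth:
    """Ground truth with representative group-mean latencies and an 8-vs-5 SD
    medial/lateral amplitude asymmetry (early larger for lateral stimulation,
    late larger for medial stimulation)."""
    entries = {}
    for g in ROI_GROUPS:
        for stim in ("medial", "lateral"):
            early_amp = 8.0 if stim == "lateral" else 5.0
            late_amp = 8.0 if stim == "medial" else 5.0
            entries[(g, stim)] = GroupResponse(
                early_latency_ms=_DEFAULT_EARLY_LAT[g],
                early_amplitude_sd=_EARLY_SIGN[g] * early_amp,
                late_latency_ms=_DEFAULT_LATE_LAT[g],
                late_amplitude_sd=late_amp,
                noise_exponent=noise_exponent,
                artifact_rate=artifact_rate,
            )
    return EpGroundTruth(entries=entries)


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, n: int,
                      alpha: float, sd: float) -> np.ndarray:
    """Gaussian 1/f^alpha noise, rescaled to unit SD per trace then to ``sd``."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x * sd


def _gauss_bump(t_ms: np.ndarray, lat_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - lat_ms) / width_ms) ** 2)


def default_channel_table(n_per_group: int = 1,
                          groups: Sequence[str] = ROI_GROUPS) -> pd.DataFrame:
    rows = []
    for g in groups:
        for k in range(n_per_group):
            rows.append(dict(name=f"{g}{k + 1}", roi=g, roi_group=g,
                             hemisphere="R", in_soz=False, in_white_matter=False))
    return pd.DataFrame(rows)


def simulate_ep_trials(gt: EpGroundTruth, n_trials: int = 60, fs: float = 8000.0,
                       seed: int = 0, stim_group: str = "medial",
                       channels: Optional[pd.DataFrame] = None,
                       noise_sd: float = 1.0, run_id: str = "run-1") -> TrialSet:
    """Simulate a stimulation run of evoked-potential trials.

    Amplitudes in the ground truth are expressed in units of the expected
    baseline SD of the *averaged* EP, so after trial rejection, averaging and
    baseline normalization the recovered peak approximates the injected value.
    With ``noise_sd == 0`` traces are emitted directly in those SD units.

    The record spans [-1000, +1000] ms around stimulation onset.  Artifact
    trials (drawn per channel at the ground-truth rate) carry either a
    saturation plateau or a large spike, both exceeding the 50-baseline-SD
    rejection bound.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz to resolve the early component")
    if channels is None:
        channels = default_channel_table()
    rng = np.random.default_rng(seed)
    n = int(round(2.0 * fs))
    t0 = n // 2
    t_ms = (np.arange(n) - t0) / fs * 1e3
    n_ch = len(channels)

    data = np.zeros((n_ch, n_trials, n))
    artifact_mask = np.zeros((n_ch, n_trials), dtype=bool)
    scale = noise_sd / np.sqrt(n_trials) if noise_sd > 0 else 1.0

    for ci, row in channels.reset_index(drop=True).iterrows():
        resp = gt.response(row["roi_group"], stim_group)
        signal = scale * (
            resp.early_amplitude_sd
            * _gauss_bump(t_ms, resp.early_latency_ms, gt.early_width_ms)
            + resp.late_amplitude_sd
            * _gauss_bump(t_ms, resp.late_latency_ms, gt.late_width_ms)
        )
        signal[t_ms < 0] = 0.0
        data[ci] = signal
        if noise_sd > 0:
            data[ci] += _one_over_f_noise(rng, (n_trials,), n,
                                          resp.noise_exponent, noise_sd)
            flags = rng.random(n_trials) < resp.artifact_rate
            artifact_mask[ci] = flags
            for ti in np.flatnonzero(flags):
                if rng.random() < 0.5:   # spike
                    at = t0 + int(rng.uniform(0.02, 0.8) * fs)
                    data[ci, ti, at:at + 8] += 80.0 * noise_sd
                else:                     # saturation plateau
                    at = t0 + int(rng.uniform(0.01, 0.5) * fs)
                    span = slice(at, at + int(0.05 * fs))
                    data[ci, ti, span] = 60.0 * noise_sd

    ts = TrialSet(data=data, fs=fs, t0_index=t0, channels=channels,
                  stim_group=stim_group, run_id=run_id, seed=seed)
    ts.ground_truth = {"ep": gt, "artifact_mask": artifact_mask,
                       "noise_sd": noise_sd}
    return ts


# ---------------------------------------------------------------------------
# vector-autoregressive oracle systems
# ---------------------------------------------------------------------------

@dataclass
class VarSpec:
    """Stationary VAR(p) specification: x_t = sum_k A_k x_{t-k} + e_t."""

    coeffs: np.ndarray       # (order, ch, ch)
    noise_cov: np.ndarray    # (ch, ch) symmetric positive-definite

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        ch = self.coeffs.shape[1]
        if self.coeffs.shape[1:] != (ch, ch) or self.noise_cov.shape != (ch, ch):
            raise ValueError("coefficient/noise dimensions inconsistent")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise covariance must be positive-definite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion(self) -> np.ndarray:
        p, ch = self.order, self.n_channels
        C = np.zeros((p * ch, p * ch))
        C[:ch, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            C[ch:, :-ch] = np.eye((p - 1) * ch)
        return C

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stationary(self) -> bool:
        return self.spectral_radius < 1.0


def var_transfer(spec: VarSpec, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Analytic transfer function H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^-1."""
    freqs = np.asarray(freqs, dtype=float)
    ch, p = spec.n_channels, spec.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    A = np.eye(ch)[None] - np.einsum("fk,kij->fij", z, spec.coeffs)
    return np.linalg.inv(A)


def var_spectral_matrix(spec: VarSpec, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Analytic two-sided cross-spectral density S(f) = H Sigma H* / fs."""
    H = var_transfer(spec, freqs, fs)
    return H @ spec.noise_cov @ np.conj(np.swapaxes(H, 1, 2)) / fs


def var_autocovariance(spec: VarSpec, n_lags: int, n_grid: int = 4096,
                       fs: float = 1.0) -> np.ndarray:
    """Autocovariance sequence Gamma_0..Gamma_{n_lags} via the spectral route."""
    freqs = np.arange(n_grid) * fs / n_grid
    S = var_spectral_matrix(spec, freqs, fs)
    gam = np.fft.ifft(S, axis=0) * fs
    return np.real(gam[: n_lags + 1])


def var_reduced_innovation_cov(spec: VarSpec, keep: Sequence[int],
                               order: int = 64) -> np.ndarray:
    """Innovation covariance of the VAR restricted to the ``keep`` channels.

    Solves the multivariate Yule-Walker equations of order ``order`` on the
    analytic autocovariances of the kept channels — a classical time-domain
    route independent of any spectral factorization code.
    """
    keep = list(keep)
    gam = var_autocovariance(spec, order)[:, keep][:, :, keep]
    k = len(keep)
    # block-Toeplitz system: sum_j A_j Gamma_{i-j} = Gamma_{i+1}
    G = np.empty((order * k, order * k))
    for i in range(order):
        for j in range(order):
            lag = i - j
            blk = gam[lag] if lag >= 0 else gam[-lag].T
            G[i * k:(i + 1) * k, j * k:(j + 1) * k] = blk.T
    rhs = np.concatenate([gam[i + 1].T for i in range(order)], axis=0)
    Acoef = np.linalg.solve(G, rhs).T.reshape(k, order, k).swapaxes(0, 1)
    sigma = gam[0].copy()
    for j in range(order):
        sigma -= Acoef[j] @ gam[j + 1].T
    return 0.5 * (sigma + sigma.T)


def var_time_domain_gc(spec: VarSpec, source: int, target: int,
                       cond: Sequence[int] = (), order: int = 64) -> float:
    """Parametric (Geweke) time-domain Granger causality source -> target.

    F = ln(var of target innovations in the model omitting the source /
    var of target innovations in the full model), conditional on ``cond``.
    """
    reduced = [target] + [c for c in cond if c not in (source, target)]
    sig_r = var_reduced_innovation_cov(spec, reduced, order=order)
    full = sorted(set(reduced) | {source})
    if len(full) == spec.n_channels:
        sig_f_tt = spec.noise_cov[target, target]
    else:
        sig_f = var_reduced_innovation_cov(spec, full, order=order)
        sig_f_tt = sig_f[full.index(target), full.index(target)]
    return float(np.log(sig_r[0, 0] / sig_f_tt))


def simulate_var(spec: VarSpec, n_trials: int, n_samples: int, seed: int = 0,
                 fs: float = 200.0, burn_in: int = 500,
                 channels: Optional[pd.DataFrame] = None) -> TrialSet:
    """Draw trials from a stationary VAR process after burn-in."""
    if not spec.is_stationary():
        raise ValueError(
            f"VAR is not stationary (companion spectral radius "
            f"{spec.spectral_radius:.3f} >= 1)")
    rng = np.random.default_rng(seed)
    ch, p = spec.n_channels, spec.order
    L = np.linalg.cholesky(spec.noise_cov)
    total = n_samples + burn_in
    data = np.zeros((ch, n_trials, n_samples))
    for ti in range(n_trials):
        e = rng.standard_normal((total, ch)) @ L.T
        x = np.zeros((total, ch))
        for t in range(p, total):
            acc = e[t].copy()
            for k in range(p):
                acc += spec.coeffs[k] @ x[t - 1 - k]
            x[t] = acc
        data[:, ti, :] = x[burn_in:].T
    if channels is None:
        groups = [ROI_GROUPS[i % len(ROI_GROUPS)] for i in range(ch)]
        channels = pd.DataFrame(dict(
            name=[f"ch{i}" for i in range(ch)], roi=groups, roi_group=groups,
            hemisphere="R", in_soz=False, in_white_matter=False))
    ts = TrialSet(data=data, fs=fs, t0_index=0, channels=channels,
                  stim_group="medial", run_id="var", seed=seed)
    ts.ground_truth = {"var": spec}
    return ts


# ---------------------------------------------------------------------------
# block-design BOLD runs
# ---------------------------------------------------------------------------

@dataclass
class BoldGroundTruth:
    """Ground truth for ROI-level block-design BOLD runs."""

    precision: np.ndarray                       # (n_roi, n_roi) SPD
    amplitudes: Dict[str, np.ndarray]           # stim_group -> (n_roi,)
    roi_names: list = field(default_factory=list)
    tr: float = 3.0
    frames_on: int = 10
    frames_off: int = 10
    n_cycles: int = 10
    lead_frames: int = 4
    noise_sd: float = 1.0
    motion_spike_prob: float = 0.02
    motion_spike_mm: float = 1.5
    baseline: float = 100.0

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        if not np.allclose(self.precision, self.precision.T):
            raise ValueError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(self.precision).min() <= 0:
            raise ValueError("precision matrix must be positive-definite")
        if not self.roi_names:
            self.roi_names = [f"roi{i}" for i in range(self.precision.shape[0])]

    @property
    def n_roi(self) -> int:
        return self.precision.shape[0]

    @property
    def n_frames(self) -> int:
        return self.lead_frames + self.n_cycles * (self.frames_on + self.frames_off)

    def partial_correlations(self) -> np.ndarray:
        """Analytic partial correlations -Omega_ij / sqrt(Omega_ii Omega_jj)."""
        d = np.sqrt(np.diag(self.precision))
        pc = -self.precision / np.outer(d, d)
        np.fill_diagonal(pc, 0.0)
        return pc


def planted_partition_precision(block_sizes: Sequence[int],
                                within: float = 0.15) -> np.ndarray:
    """Precision matrix with block-structured partial correlations ``within``
    inside each block and zero between blocks."""
    n = int(np.sum(block_sizes))
    omega = np.eye(n)
    start = 0
    for b in block_sizes:
        blk = slice(start, start + b)
        omega[blk, blk] = -within
        start += b
    np.fill_diagonal(omega, 1.0)
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("requested within-block strength is not positive-definite")
    return omega


def default_bold_ground_truth(n_roi: int = 19, within: float = 0.12,
                              **kwargs) -> BoldGroundTruth:
    """Three planted communities (sizes ~n/3) with medial/lateral amplitude
    patterns that differ most in the first and last blocks."""
    sizes = [n_roi // 3, n_roi // 3, n_roi - 2 * (n_roi // 3)]
    omega = planted_partition_precision(sizes, within=within)
    amp_med = np.full(n_roi, 1.0)
    amp_lat = np.full(n_roi, 1.0)
    amp_med[: sizes[0]] = 1.8
    amp_lat[-sizes[2]:] = 1.8
    return BoldGroundTruth(precision=omega,
                           amplitudes={"medial": amp_med, "lateral": amp_lat},
                           **kwargs)


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, under: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    from scipy.stats import gamma as _gamma
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak) - _gamma.pdf(t, under) / ratio
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


def simulate_bold(gt: BoldGroundTruth, n_runs: int, seed: int = 0,
                  stim_group: str = "medial",
                  response_in_basis: bool = False) -> list:
    """Simulate ROI-level block-design BOLD runs.

    series = baseline + amplitude x (block regressor (x) hemodynamic kernel)
    + multivariate Gaussian noise with covariance inverse(precision) + motion
    spikes.  With ``response_in_basis`` the per-block response is replaced by
    its natural-cubic-spline representation on knots [-3, 36] s (14 knots at
    TR spacing), which makes flexible-shape deconvolution exact.
    """
    rng = np.random.default_rng(seed)
    n = gt.n_frames
    amps = np.asarray(gt.amplitudes[stim_group], dtype=float)
    if amps.shape != (gt.n_roi,):
        raise ValueError("amplitude vector does not match ROI count")
    cycle = gt.frames_on + gt.frames_off
    onsets = gt.lead_frames + np.arange(gt.n_cycles) * cycle
    t = np.arange(n) * gt.tr

    block = np.zeros(n)
    for o in onsets:
        block[o:o + gt.frames_on] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 33, gt.tr))
    shape = np.convolve(block, hrf)[:n]
    if shape.max() > 0:
        shape = shape / shape.max()   # unit peak: amplitudes are peak responses
    if response_in_basis:
        knots = np.arange(-3.0, 36.1, gt.tr)
        per_block = np.zeros(n)
        ref = np.convolve(np.r_[np.ones(gt.frames_on), np.zeros(n)], hrf)[:n]
        if ref.max() > 0:
            ref = ref / ref.max()
        for o in onsets:
            rel = t - o * gt.tr
            B = cardinal_spline_basis(knots, rel)
            vals = np.interp(knots, np.arange(n) * gt.tr, ref)
            per_block += B @ vals
        shape = per_block

    cov = np.linalg.inv(gt.precision)
    runs = []
    for r in range(n_runs):
        noise = rng.multivariate_normal(np.zeros(gt.n_roi), cov, size=n).T
        noise *= gt.noise_sd
        series = gt.baseline + np.outer(amps, shape) + (noise if gt.noise_sd > 0 else 0)
        fd = np.abs(rng.normal(0.08, 0.04, size=n))
        spikes = rng.random(n) < gt.motion_spike_prob
        fd[spikes] += gt.motion_spike_mm
        if gt.noise_sd > 0:
            series[:, spikes] += rng.normal(0, 3 * gt.noise_sd,
                                            size=(gt.n_roi, spikes.sum()))
        run = BoldRun(series=series, roi_names=list(gt.roi_names), tr=gt.tr,
                      onsets=onsets, frames_on=gt.frames_on,
                      frames_off=gt.frames_off, fd=fd, stim_group=stim_group,
                      run_id=f"{stim_group}-{r + 1}", seed=seed)
        run.ground_truth = {"bold": gt, "motion_frames": np.flatnonzero(spikes)}
        runs.append(run)
    return runs
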