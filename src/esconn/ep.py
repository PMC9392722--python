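"""First-order evoked-potential analysis of stimulation-locked iEEG trials.

The stages mirror standard single-pulse CCEP practice: artifact-trial
rejection against per-trial baseline SD bounds, channel-wise averaging with
baseline-SD normalization, a zero-phase 2-200 Hz band-pass for the early
window, extraction of range / latency / polarity / trend features in the
early [10, 30) ms and late [70, 200) ms windows, a baseline-percentile
significance threshold, and group statistics (per-ROI contrasts with
Bonferroni correction; one-way ANOVA with Tukey post hoc tests on latencies).

Time 0 is stimulation onset; windows are half-open ``[a, b)`` in ms with
sample mapping ``floor(fs * t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .containers import EvokedPotential, TrialSet

EARLY_MS = (10.0, 30.0)
LATE_MS = (70.0, 200.0)
BASELINE_MS = (-100.0, -10.0)
NULL_BASELINE_MS = (-1000.0, -10.0)


# ---------------------------------------------------------------------------
# trial rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    rejected: np.ndarray            # (channels, trials) bool, True = discarded
    channel_excluded: np.ndarray    # (channels,) bool — SOZ / white matter
    zero_baseline: np.ndarray       # (channels,) bool — flagged, not silent
    thresh_at8: float = 10.0
    thresh_late: float = 50.0

    @property
    def n_rejected(self) -> int:
        return int(self.rejected[~self.channel_excluded].sum())


def reject_trials(trials: TrialSet, thresh_at8: float = 10.0,
                  thresh_late: float = 50.0) -> RejectionReport:
    """Flag artifact trials and excluded channels.

    A trial is discarded when its absolute amplitude exceeds ``thresh_at8``
    baseline SDs at 8 ms after onset (residual stimulus artifact) or
    ``thresh_late`` baseline SDs anywhere in [8, 1000] ms (saturation, cable
    motion, interictal spikes).  Baseline SD is computed per trial over
    [-100, -10) ms.  Channels inside the seizure-onset zone or in white
    matter are excluded wholesale.  Channels whose baseline SD is zero are
    flagged rather than silently passed through the amplitude rules.
    """
    base = trials.window_slice(*BASELINE_MS)
    sd = trials.data[:, :, base].std(axis=2)                  # (ch, trials)
    at8 = trials.t0_index + int(np.floor(trials.fs * 8e-3))
    late = trials.window_slice(8.0, 1000.0 + 1e3 / trials.fs)
    peak8 = np.abs(trials.data[:, :, at8])
    peak_late = np.abs(trials.data[:, :, late]).max(axis=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        rej = (peak8 > thresh_at8 * sd) | (peak_late > thresh_late * sd)
    zero_base = sd <= 0
    rej[zero_base] = False                                    # rule undefined
    excluded = (trials.channels["in_soz"].to_numpy(dtype=bool)
                | trials.channels["in_white_matter"].to_numpy(dtype=bool))
    return RejectionReport(rejected=rej, channel_excluded=excluded,
                           zero_baseline=zero_base.all(axis=1),
                           thresh_at8=thresh_at8, thresh_late=thresh_late)


# ---------------------------------------------------------------------------
# averaging and normalization
# ---------------------------------------------------------------------------

def average_normalize(trials: TrialSet,
                      report: RejectionReport | None = None) -> EvokedPotential:
    """Average retained trials per channel and normalize to baseline SD units.

    The mean trace is divided by the SD of the mean trace itself over the
    [-100, -10) ms baseline, so a normalized EP has baseline SD exactly 1.
    Degenerate channels are marked absent (``valid=False``) with a reason:
    all trials rejected, constant-zero trace, or channel excluded.  A channel
    with a nonzero trace but zero baseline SD (noiseless construction) is
    kept unnormalized and flagged.
    """
    if report is None:
        report = reject_trials(trials)
    base = trials.window_slice(*BASELINE_MS)
    n_ch, n_tr, n_s = trials.data.shape
    trace = np.zeros((n_ch, n_s))
    n_used = np.zeros(n_ch, dtype=int)
    baseline_sd = np.zeros(n_ch)
    valid = np.ones(n_ch, dtype=bool)
    reasons: dict = {}

    for c in range(n_ch):
        if report.channel_excluded[c]:
            valid[c] = False
            reasons[c] = "excluded (SOZ or white matter)"
            continue
        keep = ~report.rejected[c]
        if not keep.any():
            valid[c] = False
            reasons[c] = "all trials rejected"
            continue
        m = trials.data[c, keep].mean(axis=0)
        n_used[c] = int(keep.sum())
        sd = m[base].std()
        baseline_sd[c] = sd
        if sd > 0:
            trace[c] = m / sd
        elif np.any(m != 0):
            trace[c] = m                      # already in SD-like units
            reasons[c] = "zero baseline SD; trace left unnormalized"
        else:
            valid[c] = False
            reasons[c] = "constant-zero channel"
    return EvokedPotential(trace=trace, fs=trials.fs, t0_index=trials.t0_index,
                           channels=trials.channels, n_trials_used=n_used,
                           baseline_sd=baseline_sd, valid=valid,
                           stim_group=trials.stim_group, run_id=trials.run_id,
                           invalid_reason=reasons)


def bandpass_early(ep: EvokedPotential, low_hz: float = 2.0,
                   high_hz: float = 200.0) -> EvokedPotential:
    """Zero-phase 2nd-order Butterworth band-pass (forward-backward).

    The composed response is -6 dB at each cutoff (each pass contributes
    -3 dB), suppressing baseline drift before early-window range extraction.
    """
    if ep.fs <= 2 * high_hz:
        raise ValueError("sampling rate too low for the requested band")
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=ep.fs,
                     output="sos")
    filt = sps.sosfiltfilt(sos, ep.trace, axis=1)
    out = EvokedPotential(trace=filt, fs=ep.fs, t0_index=ep.t0_index,
                          channels=ep.channels, n_trials_used=ep.n_trials_used,
                          baseline_sd=ep.baseline_sd, valid=ep.valid,
                          stim_group=ep.stim_group, run_id=ep.run_id,
                          invalid_reason=dict(ep.invalid_reason))
    return out


def bandpass_gain_db(freq_hz: float, fs: float, low_hz: float = 2.0,
                     high_hz: float = 200.0) -> float:
    """Composed (forward-backward) gain of the early-window band-pass in dB."""
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(20 * np.log10(np.abs(h[0]) ** 2))   # two passes: |H|^2


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _earliest_extremum(x: np.ndarray, prominence: float = 1.0):
    """Index and sign of the earliest local extremum exceeding ``prominence``."""
    peaks_p, _ = sps.find_peaks(x, prominence=prominence)
    peaks_n, _ = sps.find_peaks(-x, prominence=prominence)
    cands = [(i, 1.0) for i in peaks_p] + [(i, -1.0) for i in peaks_n]
    if not cands:
        return None, None
    i, s = min(cands, key=lambda c: c[0])
    return int(i), s


def _largest_positive_peak(x: np.ndarray, prominence: float = 1.0):
    peaks, props = sps.find_peaks(x, prominence=prominence)
    if peaks.size == 0:
        return None
    return int(peaks[np.argmax(x[peaks])])


def extract_features(ep: EvokedPotential,
                     ep_filtered: EvokedPotential | None = None,
                     prominence_sd: float = 1.0) -> pd.DataFrame:
    """Range, latency, polarity and trend per channel and window.

    Early-window features are measured on the band-passed trace; the late
    positive component (P150) on the raw normalized trace.  Channels without
    a local extremum of at least ``prominence_sd`` SD prominence get polarity
    ``absent`` and NaN latency (absence is a value, not an error).
    """
    if ep_filtered is None:
        ep_filtered = bandpass_early(ep)
    t_ms = ep.times_ms
    rows = []
    for c in range(ep.trace.shape[0]):
        meta = dict(channel=ep.channels["name"].iloc[c],
                    roi=ep.channels["roi"].iloc[c],
                    roi_group=ep.channels["roi_group"].iloc[c],
                    stim_group=ep.stim_group, run_id=ep.run_id)
        if not ep.valid[c]:
            for w in ("early", "late"):
                rows.append(dict(meta, window=w, range_value=np.nan,
                                 peak_latency_ms=np.nan, polarity="absent",
                                 trend_value=np.nan, valid=False))
            continue
        # early window, band-passed trace
        sl = ep.window_slice(*EARLY_MS)
        xe = ep_filtered.trace[c, sl]
        idx, sign = _earliest_extremum(xe, prominence_sd)
        rows.append(dict(
            meta, window="early",
            range_value=float(xe.max() - xe.min()),
            peak_latency_ms=float(t_ms[sl][idx]) if idx is not None else np.nan,
            polarity=("P" if sign > 0 else "N") if idx is not None else "absent",
            trend_value=float(xe[-1] - xe[0]), valid=True))
        # late window, raw normalized trace
        sl = ep.window_slice(*LATE_MS)
        xl = ep.trace[c, sl]
        pk = _largest_positive_peak(xl, prominence_sd)
        rows.append(dict(
            meta, window="late",
            range_value=float(xl.max() - xl.min()),
            peak_latency_ms=float(t_ms[sl][pk]) if pk is not None else np.nan,
            polarity="P" if pk is not None else "absent",
            trend_value=float(xl[-1] - xl[0]), valid=True))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# significance against the baseline null
# ---------------------------------------------------------------------------

def baseline_range_threshold(trace: np.ndarray, fs: float, t0: int,
                             window_ms: float, step_ms: float = 10.0,
                             q: float = 95.0) -> float:
    """95th percentile of range values in sliding baseline windows.

    The [-1000, -10) ms baseline is tiled with windows equal in length to the
    analysis window, stepped by ``step_ms``; the range (max - min) of each
    window forms the null amplitude histogram.
    """
    a = t0 + int(np.floor(fs * NULL_BASELINE_MS[0] / 1e3))
    b = t0 + int(np.floor(fs * NULL_BASELINE_MS[1] / 1e3))
    if a < 0:
        raise ValueError("insufficient baseline: need 990 ms before -10 ms")
    w = int(np.floor(fs * window_ms / 1e3))
    step = int(np.floor(fs * step_ms / 1e3))
    seg = trace[a:b]
    if seg.size < w:
        raise ValueError("baseline shorter than the analysis window")
    starts = np.arange(0, seg.size - w + 1, step)
    windows = seg[starts[:, None] + np.arange(w)[None, :]]
    ranges = windows.max(axis=1) - windows.min(axis=1)
    # 'higher' keeps the exceedance probability of a new window at ~(1 - q):
    # interpolated quantiles of ~100 pooled ranges sit low and over-fire
    return float(np.percentile(ranges, q, method="higher"))


def significance_test(ep: EvokedPotential, features: pd.DataFrame,
                      ep_filtered: EvokedPotential | None = None,
                      q: float = 95.0) -> pd.DataFrame:
    """Attach baseline-percentile thresholds and significance flags.

    A channel/window is significant when its post-stimulus range exceeds the
    95th percentile of range values from matched-length sliding baseline
    windows (early thresholds from the band-passed trace, late from the raw
    trace).
    """
    if ep_filtered is None:
        ep_filtered = bandpass_early(ep)
    out = features.copy()
    out["threshold"] = np.nan
    out["is_significant"] = False
    win_len = {"early": EARLY_MS[1] - EARLY_MS[0], "late": LATE_MS[1] - LATE_MS[0]}
    names = list(ep.channels["name"])
    for c, name in enumerate(names):
        if not ep.valid[c]:
            continue
        for w, src in (("early", ep_filtered), ("late", ep)):
            thr = baseline_range_threshold(src.trace[c], ep.fs, ep.t0_index,
                                           win_len[w], q=q)
            m = (out["channel"] == name) & (out["window"] == w)
            out.loc[m, "threshold"] = thr
            out.loc[m, "is_significant"] = out.loc[m, "range_value"] > thr
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def roi_contrast(features: pd.DataFrame, group_col: str = "stim_group",
                 roi_col: str = "roi", value_col: str = "range_value",
                 effect_size_only: bool = False) -> pd.DataFrame:
    """Per-ROI two-group contrast on range values.

    Two-sided t-tests per ROI with Bonferroni correction over the number of
    testable ROIs; ROIs with fewer than two samples in either group are
    marked untestable.  In ``effect_size_only`` mode (sex / hemisphere
    descriptive contrasts) no hypothesis test is performed and only the mean
    difference and its standard error are reported.
    """
    levels = sorted(features[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two levels of {group_col}, got {levels}")
    rows = []
    for roi, sub in features.groupby(roi_col):
        a = sub.loc[sub[group_col] == levels[0], value_col].dropna().to_numpy()
        b = sub.loc[sub[group_col] == levels[1], value_col].dropna().to_numpy()
        testable = a.size >= 2 and b.size >= 2
        diff = a.mean() - b.mean() if a.size and b.size else np.nan
        se = (np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
              if testable else np.nan)
        row = dict(roi=roi, n_a=a.size, n_b=b.size, mean_diff=diff, se=se,
                   testable=testable)
        if not effect_size_only and testable:
            t, p = spstats.ttest_ind(a, b)
            row.update(t=float(t), p=float(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    if not effect_size_only:
        m = int(out.get("testable", pd.Series(dtype=bool)).sum())
        if "p" in out:
            out["p_bonferroni"] = np.minimum(1.0, out["p"] * m)
        out.attrs["n_tests"] = m
    return out


def latency_group_stats(features: pd.DataFrame, group_col: str = "roi_group",
                        value_col: str = "peak_latency_ms"):
    """One-way ANOVA over peak latencies with Tukey HSD post hoc tests.

    Returns ``(anova_dict, tukey_dataframe)``.  Groups with fewer than two
    latencies are dropped with a warning entry; fewer than two usable groups
    is an error.
    """
    import warnings
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    clean = features.dropna(subset=[value_col])
    samples, labels = [], []
    for g, sub in clean.groupby(group_col):
        v = sub[value_col].to_numpy()
        if v.size < 2:
            warnings.warn(f"group {g!r} dropped ({v.size} latencies)")
            continue
        samples.append(v)
        labels.append(g)
    if len(samples) < 2:
        raise ValueError("need at least two groups with >= 2 latencies")
    F, p = spstats.f_oneway(*samples)
    n = sum(v.size for v in samples)
    anova = dict(F=float(F), p=float(p), df_between=len(samples) - 1,
                 df_within=n - len(samples),
                 group_means={g: float(v.mean()) for g, v in zip(labels, samples)})
    values = np.concatenate(samples)
    groups = np.concatenate([[g] * v.size for g, v in zip(labels, samples)])
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova, tukey
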