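"""End-to-end validation experiments at study conditions.

Each function simulates inputs with known ground truth, runs the relevant
pipeline stage(s), and returns a small dict of metrics plus the problem size
``n`` used.  These are the package's self-contained correctness checks: the
printed stimulus arithmetic, the filter response, oracle equivalence of the
nonparametric Granger estimator, null calibrations of the three significance
procedures, parameter recovery, and deconvolution exactness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bold as eb
from . import cgc as ec
from . import classify as ecl
from . import ep as eep
from . import stimulus as est
from .synthetic import (VarSpec, default_bold_ground_truth,
                        default_channel_table, default_ep_ground_truth,
                        simulate_bold, simulate_ep_trials, simulate_var,
                        var_time_domain_gc)


def charge_metrics() -> dict:
    """Charge per phase and total duration of the printed stimulus waveform
    (9 mA, 0.2 ms per phase, charge-balanced biphasic)."""
    return dict(
        charge_per_phase_uc=est.charge_per_phase_uc(9.0, 0.2),
        pulse_total_duration_ms=est.biphasic_total_duration_ms(0.2),
        n=1)


def filter_metrics(fs: float = 8000.0) -> dict:
    """Composed (zero-phase) band-pass attenuation at the 2 / 200 Hz cutoffs."""
    return dict(
        attenuation_db_2hz=-eep.bandpass_gain_db(2.0, fs),
        attenuation_db_200hz=-eep.bandpass_gain_db(200.0, fs),
        n=int(fs))


def gc_oracle_metrics(seed: int = 0, n_trials: int = 100,
                      n_samples: int = 2000) -> dict:
    """Oracle equivalence: nonparametric spectral GC vs parametric Geweke GC
    on a bivariate VAR with one-way coupling."""
    A = np.zeros((2, 2, 2))
    A[0] = [[0.55, 0.0], [0.45, 0.5]]
    A[1] = [[-0.8, 0.0], [0.0, -0.2]]
    spec = VarSpec(A, np.eye(2))
    F = var_time_domain_gc(spec, 0, 1)
    ts = simulate_var(spec, n_trials=n_trials, n_samples=n_samples, seed=seed,
                      fs=200.0)
    S = ec.estimate_csd(ts, window_ms=(0, n_samples / ts.fs * 1e3))
    g = ec.pairwise_gc(S, 0, 1)
    rev = ec.pairwise_gc(S, 1, 0)
    return dict(rel_err_pct=abs(g.mean() - F) / F * 100.0,
                spectral_mean=float(g.mean()), parametric=F,
                reverse_gc=float(rev.mean()), n=n_trials * n_samples)


def chain_null_metrics(seed: int = 0, n_trials: int = 100,
                       n_samples: int = 2000, n_surr: int = 60,
                       nfft: int = 512) -> dict:
    """Chain x->y->z: conditional x->z|y at 8 Hz against the phase-randomized
    surrogate threshold (ratio < 1 means indistinguishable from the null)."""
    A = np.zeros((1, 3, 3))
    A[0] = [[0.5, 0, 0], [0.6, 0.4, 0], [0, 0.6, 0.3]]
    spec = VarSpec(A, np.eye(3))
    ts = simulate_var(spec, n_trials=n_trials, n_samples=n_samples, seed=seed,
                      fs=200.0)
    win = (0, n_samples / ts.fs * 1e3)
    S = ec.estimate_csd(ts, window_ms=win, nfft=nfft)
    res = ec.cgc_matrix(S, channels=ts.channels)
    thr = ec.surrogate_threshold(ts, window_ms=win, n_surr=n_surr,
                                 seed=seed + 1, nfft=nfft)
    b = int(np.argmin(np.abs(S.freqs - 8.0)))
    return dict(cond_xz=float(res.cgc[0, 2, b]),
                threshold=float(thr[0, 2, b]),
                ratio=float(res.cgc[0, 2, b] / thr[0, 2, b]),
                pairwise_xy=float(res.cgc[0, 1, b]), n=n_surr)


def ep_false_positive_rate(seed: int = 0, n_channels: int = 1000,
                           fs: float = 1000.0) -> dict:
    """Fraction of pure-noise channels whose early-window range exceeds the
    95th-percentile baseline threshold (expected ~5%)."""
    rng = np.random.default_rng(seed)
    n = int(2.2 * fs)
    t0 = n // 2
    hits = 0
    for _ in range(n_channels):
        x = rng.standard_normal(n)
        thr = eep.baseline_range_threshold(x, fs, t0, 20.0)
        sl = slice(t0 + int(0.010 * fs), t0 + int(0.030 * fs))
        hits += (x[sl].max() - x[sl].min()) > thr
    return dict(false_positive_pct=hits / n_channels * 100.0, n=n_channels)


def cgc_null_exceedance(seed: int = 0, n_datasets: int = 25,
                        n_surr: int = 60) -> dict:
    """Exceedance of true CGC over the per-dataset surrogate threshold at the
    8 Hz bin for independent channels (expected ~5%)."""
    spec = VarSpec(np.zeros((1, 2, 2)), np.eye(2))
    hits = total = 0
    for d in range(n_datasets):
        ts = simulate_var(spec, n_trials=30, n_samples=256,
                          seed=seed + 1000 + d, fs=200.0)
        S = ec.estimate_csd(ts, window_ms=(0, 1280), nfft=256)
        res = ec.cgc_matrix(S, channels=ts.channels)
        thr = ec.surrogate_threshold(ts, window_ms=(0, 1280), n_surr=n_surr,
                                     seed=seed + d, nfft=256)
        b = int(np.argmin(np.abs(S.freqs - 8.0)))
        for s, t in [(0, 1), (1, 0)]:
            hits += res.cgc[s, t, b] > thr[s, t, b]
            total += 1
    return dict(exceedance_pct=hits / total * 100.0, n=total)


def fdr_null_rate(seed: int = 0, n_repeats: int = 4, n_runs: int = 8) -> dict:
    """Fraction of edges called significant when contrasting ON vs OFF
    networks of stimulation-free (null) BOLD runs (expected <= ~5%)."""
    gt = default_bold_ground_truth()
    gt.amplitudes["medial"][:] = 0.0         # no stimulation effect
    fracs = []
    for r in range(n_repeats):
        runs = [eb.fir_deconvolve(run)
                for run in simulate_bold(gt, n_runs, seed=seed + 50 * r)]
        on = [eb.residual_network(run, "ON") for run in runs]
        off = [eb.residual_network(run, "OFF") for run in runs]
        out = eb.edge_contrast(on, off)
        fracs.append(out.significant.mean())
    return dict(false_edge_pct=float(np.mean(fracs)) * 100.0,
                n=n_repeats * n_runs)


def latency_recovery_metrics(seed: int = 0, n_runs: int = 2,
                             n_per_group: int = 6, fs: float = 8000.0) -> dict:
    """Recovery of injected ROI-group early-latency values and ordering from
    lateral-stimulation runs."""
    gt = default_ep_ground_truth(artifact_rate=0.05)
    chan = default_channel_table(n_per_group=n_per_group)
    frames = []
    for r in range(n_runs):
        ts = simulate_ep_trials(gt, n_trials=60, fs=fs, seed=seed + r,
                                stim_group="lateral", channels=chan,
                                run_id=f"run-{r}")
        ep = eep.average_normalize(ts, eep.reject_trials(ts))
        frames.append(eep.extract_features(ep, eep.bandpass_early(ep)))
    feats = pd.concat(frames, ignore_index=True)
    early = feats[feats.window == "early"].dropna(subset=["peak_latency_ms"])
    errs, means = {}, {}
    for g, sub in early.groupby("roi_group"):
        inj = gt.response(g, "lateral").early_latency_ms
        means[g] = sub.peak_latency_ms.mean()
        errs[g] = means[g] - inj
    inj_order = sorted(means, key=lambda g:
                       gt.response(g, "lateral").early_latency_ms)
    got_order = sorted(means, key=means.get)
    anova, _ = eep.latency_group_stats(early)
    return dict(max_abs_error_ms=float(max(abs(e) for e in errs.values())),
                ordering_recovered=float(got_order == inj_order),
                anova_p=anova["p"], group_means=means,
                n=len(early))


def community_recovery_ari(seed: int = 0, n_runs_bold: int = 4,
                           n_cycles: int = 40, n_leiden: int = 200) -> dict:
    """Consensus clustering of the mean estimated residual network recovers
    the planted three-community precision structure (ARI = 1)."""
    from sklearn.metrics import adjusted_rand_score

    gt = default_bold_ground_truth(n_cycles=n_cycles)
    runs = [eb.fir_deconvolve(r)
            for r in simulate_bold(gt, n_runs_bold, seed=seed)]
    nets = ([eb.residual_network(r, "ON") for r in runs]
            + [eb.residual_network(r, "OFF") for r in runs])
    z = np.mean([n.z for n in nets], axis=0)
    memb = eb.community_consensus(z, n_runs=n_leiden, seed=seed)
    sizes = [19 // 3, 19 // 3, 19 - 2 * (19 // 3)]
    truth = np.concatenate([[k] * s for k, s in enumerate(sizes)])
    return dict(ari=float(adjusted_rand_score(truth, memb)),
                n_communities=len(set(memb)), n=n_runs_bold * gt.n_frames)


def decoding_metrics(seed: int = 0, n_runs_per_group: int = 8,
                     n_per_group: int = 2, fs: float = 2000.0,
                     n_shuffles: int = 5) -> dict:
    """Stimulation-site decoding from EP features across runs: accuracy with
    the five headline features and the shuffled-label chance level."""
    gt = default_ep_ground_truth(artifact_rate=0.05)
    chan = default_channel_table(n_per_group=n_per_group)
    frames = []
    for r in range(n_runs_per_group):
        for sg in ("medial", "lateral"):
            ts = simulate_ep_trials(gt, n_trials=60, fs=fs,
                                    seed=seed + 2 * r + (sg == "lateral"),
                                    stim_group=sg, channels=chan,
                                    run_id=f"{sg}-{r}")
            ep = eep.average_normalize(ts, eep.reject_trials(ts))
            frames.append(eep.extract_features(ep, eep.bandpass_early(ep)))
    feats = pd.concat(frames, ignore_index=True)
    table = ecl.feature_table(feats)
    curve = ecl.sequential_feature_classification(
        table, folds=10, seed=seed, grouping="run", n_shuffles=n_shuffles,
        feature_order=("range_early", "range_late", "lat_early", "lat_late",
                       "roi"))
    last = curve.iloc[-1]
    return dict(accuracy_pct=float(last.accuracy) * 100.0,
                shuffled_pct=float(last.shuffled_accuracy) * 100.0,
                n=len(table))


def deconvolution_metrics(seed: int = 0) -> dict:
    """Deconvolution exactness on noiseless runs whose response lies in the
    spline span, and mean-beta linearity (2x amplitude -> 2x mean beta)."""
    gt = default_bold_ground_truth(noise_sd=0.0, motion_spike_prob=0.0)
    gt.amplitudes["medial"] = np.ones(19)
    gt.amplitudes["medial"][4] = 2.0
    run = eb.fir_deconvolve(simulate_bold(gt, 1, seed=seed,
                                          response_in_basis=True)[0])
    mb = eb.mean_beta(run)
    return dict(max_abs_residual=float(np.abs(run.residuals).max()),
                mean_beta_ratio=float(mb[4] / mb[0]), n=run.n_frames)
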