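"""EP quantification: rejection rules, normalization, filtering, features,
significance calibration and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esconn.containers import TrialSet
from esconn.ep import (average_normalize, bandpass_early, bandpass_gain_db,
                       baseline_range_threshold, extract_features,
                       latency_group_stats, reject_trials, roi_contrast,
                       significance_test)
from esconn.synthetic import default_channel_table


def _single_channel(data_1trial, fs=1000.0):
    """Wrap (trials, samples) data as a one-channel TrialSet, onset mid-record."""
    arr = np.asarray(data_1trial, dtype=float)[None, :, :]
    return TrialSet(data=arr, fs=fs, t0_index=arr.shape[2] // 2,
                    channels=default_channel_table(1, ["OF"]))


def _noise_trials(rng, n_trials=10, fs=1000.0, dur_s=2.2):
    return rng.standard_normal((n_trials, int(dur_s * fs)))


class TestRejectTrials:
    def test_spike_at_8ms_rejected(self):
        rng = np.random.default_rng(0)
        x = _noise_trials(rng)
        ts = _single_channel(x)
        at8 = ts.t0_index + 8  # 8 ms at 1 kHz
        ts.data[0, 3, at8] = 11.0 * ts.data[0, 3, ts.window_slice(-100, -10)].std()
        rep = reject_trials(ts)
        assert rep.rejected[0, 3]
        assert rep.rejected.sum() == 1

    def test_subthreshold_trial_retained(self):
        rng = np.random.default_rng(1)
        x = _noise_trials(rng)
        ts = _single_channel(x)
        sd = ts.data[0, 2, ts.window_slice(-100, -10)].std()
        ts.data[0, 2, ts.t0_index + 500] = 49.0 * sd
        ts.data[0, 2, ts.t0_index + 8] = 9.0 * sd
        assert not reject_trials(ts).rejected[0, 2]

    def test_late_spike_rejected(self):
        rng = np.random.default_rng(2)
        ts = _single_channel(_noise_trials(rng))
        sd = ts.data[0, 5, ts.window_slice(-100, -10)].std()
        ts.data[0, 5, ts.t0_index + 500] = 51.0 * sd
        assert reject_trials(ts).rejected[0, 5]

    def test_rejected_count_matches_injected_artifacts(self, ep_run):
        rep = reject_trials(ep_run)
        np.testing.assert_array_equal(rep.rejected,
                                      ep_run.ground_truth["artifact_mask"])

    def test_soz_and_white_matter_excluded(self):
        chan = default_channel_table(3, ["OF"])
        chan.loc[0, "in_soz"] = True
        chan.loc[2, "in_white_matter"] = True
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 5, 2200))
        ts = TrialSet(data=data, fs=1000, t0_index=1100, channels=chan)
        rep = reject_trials(ts)
        assert list(rep.channel_excluded) == [True, False, True]
        ep = average_normalize(ts, rep)
        assert not ep.valid[0] and ep.valid[1] and not ep.valid[2]

    def test_zero_baseline_flagged_not_silent(self):
        data = np.zeros((1, 4, 2200))
        data[:, :, 1120] = 5.0
        ts = TrialSet(data=data, fs=1000, t0_index=1100,
                      channels=default_channel_table(1, ["OF"]))
        rep = reject_trials(ts)
        assert rep.zero_baseline[0]
        assert not rep.rejected.any()

    @settings(max_examples=20, deadline=None)
    @given(lo=st.floats(2.0, 20.0), hi=st.floats(20.0, 80.0))
    def test_rejection_monotone_in_thresholds(self, lo, hi):
        """Raising either threshold never rejects more trials."""
        rng = np.random.default_rng(17)
        ts = _single_channel(5 * _noise_trials(rng, n_trials=20))
        strict = reject_trials(ts, thresh_at8=lo, thresh_late=hi)
        loose = reject_trials(ts, thresh_at8=lo * 1.5, thresh_late=hi * 1.5)
        assert not (loose.rejected & ~strict.rejected).any()


class TestAverageNormalize:
    def test_unit_baseline_sd(self, ep_run):
        ep = average_normalize(ep_run)
        base = ep.window_slice(-100, -10)
        np.testing.assert_allclose(ep.trace[ep.valid, base].std(axis=1), 1.0,
                                   atol=1e-6)

    def test_idempotence(self, ep_run):
        ep = average_normalize(ep_run)
        renorm = TrialSet(data=ep.trace[:, None, :], fs=ep.fs,
                          t0_index=ep.t0_index, channels=ep.channels)
        ep2 = average_normalize(renorm)
        np.testing.assert_allclose(ep2.trace[ep.valid], ep.trace[ep.valid],
                                   rtol=1e-9)

    def test_injected_bump_scales_as_a_over_s(self):
        """Bump of A volts on noise with baseline SD s -> peak ~ A/s."""
        rng = np.random.default_rng(5)
        n, fs = 2200, 1000.0
        A, s = 12.0, 2.0
        x = rng.standard_normal((40, n)) * s
        bump = A * np.exp(-0.5 * ((np.arange(n) - 1120) / 5.0) ** 2)
        ts = _single_channel(x + bump, fs=fs)
        ep = average_normalize(ts)
        expect = A / (s / np.sqrt(ep.n_trials_used[0]))
        assert ep.trace[0].max() == pytest.approx(expect, rel=0.15)

    def test_constant_zero_channel_absent_with_reason(self):
        ts = _single_channel(np.zeros((3, 2200)))
        ep = average_normalize(ts)
        assert not ep.valid[0]
        assert "zero" in ep.invalid_reason[0]

    def test_noiseless_normalization_is_flagged_noop(self, noiseless_run):
        ep = average_normalize(noiseless_run)
        assert ep.valid[0]
        assert "unnormalized" in ep.invalid_reason[0]
        sl = ep.window_slice(10, 30)
        assert ep.trace[0, sl].max() == pytest.approx(8.0, rel=1e-3)


class TestBandpass:
    @pytest.mark.parametrize("f", [2.0, 200.0])
    def test_minus_6db_at_cutoffs(self, f):
        assert bandpass_gain_db(f, fs=8000.0) == pytest.approx(-6.0, abs=0.1)

    def test_passband_flat_at_30hz(self):
        assert abs(bandpass_gain_db(30.0, fs=8000.0)) < 0.5

    def test_zero_phase_preserves_symmetry(self):
        """A symmetric pulse stays symmetric under forward-backward filtering.

        The record is long enough for the slow 2 Hz pole to settle, and the
        comparison stays away from the edges where padding transients live.
        """
        n, fs = 64001, 8000.0           # odd length: exact reversal symmetry
        c = n // 2
        pulse = np.exp(-0.5 * ((np.arange(n) - c) / 40.0) ** 2)
        from esconn.containers import EvokedPotential
        ep = EvokedPotential(trace=pulse[None, :], fs=fs, t0_index=c,
                             channels=default_channel_table(1, ["OF"]),
                             n_trials_used=np.array([1]),
                             baseline_sd=np.array([1.0]),
                             valid=np.array([True]))
        y = bandpass_early(ep).trace[0]
        core = y[c - 16000: c + 16001]
        np.testing.assert_allclose(core, core[::-1],
                                   atol=1e-6 * np.abs(y).max())


class TestFeatures:
    def test_full_sine_cycle_range_two(self):
        fs = 8000.0
        n = int(2.2 * fs)
        t = (np.arange(n) - n // 2) / fs
        x = np.sin(2 * np.pi * 100 * t)  # 100 Hz: full cycles inside windows
        ts = _single_channel(np.tile(x, (3, 1)), fs=fs)
        ep = average_normalize(ts)
        raw = ep.trace[0] * 0 + x / x[ep.window_slice(-100, -10)].std()
        # range on the raw late window of a sine = 2 x amplitude (in SD units)
        sl = ep.window_slice(70, 200)
        amp = 1 / x[ep.window_slice(-100, -10)].std()
        assert raw[sl].max() - raw[sl].min() == pytest.approx(2 * amp, rel=1e-3)

    def test_noiseless_latency_and_polarity(self, noiseless_run):
        ep = average_normalize(noiseless_run)
        feats = extract_features(ep)
        early = feats[feats.window == "early"].iloc[0]
        assert early.peak_latency_ms == pytest.approx(15.0, abs=0.2)
        assert early.polarity == "P"
        late = feats[feats.window == "late"].iloc[0]
        assert late.polarity == "absent"
        assert np.isnan(late.peak_latency_ms)

    def test_range_offset_invariance_and_scaling(self, ep_run):
        """Range is invariant to constant offsets and linear in amplitude."""
        ep = average_normalize(ep_run)
        f1 = extract_features(ep)
        ep_scaled = average_normalize(ep_run)
        ep_scaled.trace = 3.0 * ep.trace + 7.0
        f3 = extract_features(ep_scaled, bandpass_early(ep_scaled))
        v = f1.range_value.to_numpy()
        np.testing.assert_allclose(f3.range_value.to_numpy(), 3.0 * v,
                                   rtol=1e-6)

    def test_latency_recovery_within_half_ms(self, ep_run):
        """Group-mean early latency (pooled over runs) recovers the injected
        value to 0.5 ms."""
        from esconn.synthetic import simulate_ep_trials

        gt = ep_run.ground_truth["ep"]
        chan = default_channel_table(n_per_group=6)
        frames = []
        for s in (12, 13):
            run = simulate_ep_trials(gt, n_trials=60, fs=8000, seed=s,
                                     stim_group="lateral", channels=chan,
                                     run_id=f"run-{s}")
            ep = average_normalize(run, reject_trials(run))
            frames.append(extract_features(ep, bandpass_early(ep)))
        feats = pd.concat(frames, ignore_index=True)
        early = feats[(feats.window == "early")].dropna(
            subset=["peak_latency_ms"])
        for g, sub in early.groupby("roi_group"):
            inj = gt.response(g, "lateral").early_latency_ms
            assert sub.peak_latency_ms.mean() == pytest.approx(inj, abs=0.5)


class TestSignificance:
    def test_flat_trace_not_significant(self):
        ts = _single_channel(np.zeros((3, 2200)))
        ts.data[0, :, 1150] = 1.0  # make baseline nonzero via one blip? no:
        ts.data[0] += np.random.default_rng(0).standard_normal((3, 2200)) * 1e-12
        ep = average_normalize(ts)
        thr = baseline_range_threshold(ep.trace[0], ep.fs, ep.t0_index, 20.0)
        assert thr >= 0.0

    def test_injected_component_significant(self, ep_run):
        """8-SD components clear the 95th-percentile baseline threshold:
        early under lateral stimulation, late under medial stimulation."""
        from esconn.synthetic import simulate_ep_trials

        ep = average_normalize(ep_run, reject_trials(ep_run))
        epf = bandpass_early(ep)
        feats = significance_test(ep, extract_features(ep, epf), epf)
        assert feats[feats.window == "early"].is_significant.all()

        gt = ep_run.ground_truth["ep"]  # medial stimulation: late amp 8 SD
        med = simulate_ep_trials(gt, n_trials=60, fs=8000, seed=31,
                                 stim_group="medial",
                                 channels=ep_run.channels)
        epm = average_normalize(med, reject_trials(med))
        epmf = bandpass_early(epm)
        fm = significance_test(epm, extract_features(epm, epmf), epmf)
        assert fm[fm.window == "late"].is_significant.all()

    def test_insufficient_baseline_errors(self):
        short = np.random.default_rng(0).standard_normal(500)
        with pytest.raises(ValueError, match="baseline"):
            baseline_range_threshold(short, 1000.0, 400, 20.0)

    def test_false_positive_rate_calibrated(self):
        """95th-percentile baseline threshold fires ~5% on pure noise."""
        rng = np.random.default_rng(42)
        n_ch, fs = 400, 1000.0
        n = int(2.2 * fs)
        hits = 0
        for c in range(n_ch):
            x = rng.standard_normal(n)
            thr = baseline_range_threshold(x, fs, n // 2, 20.0)
            sl = slice(n // 2 + 10, n // 2 + 30)
            rng_val = x[sl].max() - x[sl].min()
            hits += rng_val > thr
        assert hits / n_ch == pytest.approx(0.05, abs=0.025)


class TestGroupStats:
    def _features(self, rng, n=20, delta=0.0, rois=("A", "B")):
        rows = []
        for roi in rois:
            for g in ("medial", "lateral"):
                for _ in range(n):
                    shift = delta if (g == "medial" and roi == rois[0]) else 0.0
                    rows.append(dict(roi=roi, stim_group=g,
                                     range_value=rng.normal(shift, 1.0)))
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero(self):
        df = pd.DataFrame(dict(roi=["A"] * 8,
                               stim_group=["medial", "lateral"] * 4,
                               range_value=[1.0, 1.0, 2.0, 2.0] * 2))
        out = roi_contrast(df)
        assert out.t.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out.p_bonferroni.iloc[0] == 1.0

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(0)
        df = self._features(rng, rois=tuple("ABCDE"))
        out = roi_contrast(df)
        m = out.attrs["n_tests"]
        np.testing.assert_allclose(out.p_bonferroni,
                                   np.minimum(1.0, out.p * m))

    def test_only_injected_roi_survives_correction(self):
        rng = np.random.default_rng(1)
        df = self._features(rng, n=30, delta=3.0, rois=tuple("ABCDEFGHIJ"))
        out = roi_contrast(df)
        sig = out[out.p_bonferroni < 0.05]
        assert list(sig.roi) == ["A"]

    def test_effect_size_only_mode_has_no_p(self):
        rng = np.random.default_rng(2)
        out = roi_contrast(self._features(rng), effect_size_only=True)
        assert "p" not in out.columns and "mean_diff" in out.columns

    def test_latency_ordering_recovered(self):
        rng = np.random.default_rng(3)
        means = dict(OF=15.0, lPFC=17.0, TL=19.0, PL=21.0)
        rows = [dict(roi_group=g, peak_latency_ms=rng.normal(m, 0.5))
                for g, m in means.items() for _ in range(25)]
        anova, tukey = latency_group_stats(pd.DataFrame(rows))
        assert anova["p"] < 1e-6
        got = sorted(anova["group_means"], key=anova["group_means"].get)
        assert got == ["OF", "lPFC", "TL", "PL"]

    def test_single_group_errors(self):
        df = pd.DataFrame(dict(roi_group=["OF"] * 5,
                               peak_latency_ms=np.arange(5.0) + 14))
        with pytest.raises(ValueError, match="two groups"):
            latency_group_stats(df)
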