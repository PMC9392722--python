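"""Quantify evoked potentials from one simulated stimulation run.

Simulates a lateral-amygdala stimulation run (60 single pulses, 8 kHz, two
contacts per anatomical ROI group, 5% artifact trials), rejects artifact
trials, averages and baseline-normalizes, and extracts the early (N/P15)
and late (P150) component features with significance flags.
"""

from esconn.ep import (average_normalize, bandpass_early, extract_features,
                       reject_trials, significance_test)
from esconn.synthetic import (default_channel_table, default_ep_ground_truth,
                              simulate_ep_trials)

gt = default_ep_ground_truth(artifact_rate=0.05)
run = simulate_ep_trials(gt, n_trials=60, fs=8000, seed=1,
                         stim_group="lateral",
                         channels=default_channel_table(n_per_group=2))

report = reject_trials(run)
print(f"trials rejected: {report.n_rejected} "
      f"(injected artifacts: {run.ground_truth['artifact_mask'].sum()})")

ep = average_normalize(run, report)
ep_filt = bandpass_early(ep)
feats = significance_test(ep, extract_features(ep, ep_filt), ep_filt)

cols = ["channel", "roi_group", "window", "range_value", "peak_latency_ms",
        "polarity", "is_significant"]
print(feats[cols].round(2).to_string(index=False))
print("\nrange_value is max-minus-min amplitude in baseline-SD units; a row "
      "is significant when its range exceeds the 95th percentile of "
      "matched-length baseline windows. Early peaks cluster near the "
      "injected 17-21 ms group latencies; the late positive peak sits "
      "near 130-160 ms.")
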