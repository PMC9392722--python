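"""Decode the stimulated amygdala subdivision from EP features.

Simulates medial- and lateral-stimulation runs (the two subdivisions differ
in early/late amplitude and latency profiles), quantifies EP features, and
trains the gradient-boosted classifier with features added sequentially,
next to a shuffled-label control.
"""

import pandas as pd

from esconn.classify import feature_table, sequential_feature_classification
from esconn.ep import (average_normalize, bandpass_early, extract_features,
                       reject_trials)
from esconn.synthetic import (default_channel_table, default_ep_ground_truth,
                              simulate_ep_trials)

gt = default_ep_ground_truth(artifact_rate=0.05)
chan = default_channel_table(n_per_group=2)
frames = []
for r in range(6):
    for sg in ("medial", "lateral"):
        run = simulate_ep_trials(gt, n_trials=60, fs=2000,
                                 seed=10 + 2 * r + (sg == "lateral"),
                                 stim_group=sg, channels=chan,
                                 run_id=f"{sg}-{r}")
        ep = average_normalize(run, reject_trials(run))
        frames.append(extract_features(ep, bandpass_early(ep)))

table = feature_table(pd.concat(frames, ignore_index=True))
curve = sequential_feature_classification(
    table, folds=10, seed=0, grouping="run", n_shuffles=2,
    feature_order=("range_early", "range_late", "lat_early", "lat_late",
                   "roi"))
print(curve[["n_features", "features", "accuracy",
             "shuffled_accuracy"]].round(3).to_string(index=False))
print("\nAccuracy is 10-fold cross-validated (folds grouped by run) for "
      "medial-vs-lateral decoding; it passes 80% once ranges and latencies "
      "of both windows are in, while the label-shuffled control stays at "
      "chance (~50%).")
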