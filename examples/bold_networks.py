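"""Second-order connectivity from simulated es-fMRI runs.

Simulates block-design BOLD runs whose noise covariance encodes three
planted partial-correlation communities, deconvolves the evoked response
with the 14-knot spline basis, builds Fisher-z partial-correlation networks
from the residuals (ON and OFF frames separately), and recovers the planted
communities by consensus Leiden clustering.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from esconn.bold import (community_consensus, fir_deconvolve, mean_beta,
                         residual_network)
from esconn.synthetic import default_bold_ground_truth, simulate_bold

gt = default_bold_ground_truth(n_cycles=40)
runs = [fir_deconvolve(r) for r in simulate_bold(gt, 4, seed=5)]

mb = np.mean([mean_beta(r) for r in runs], axis=0)
print("mean beta (percent signal, 3-30 s window), first 6 ROIs:",
      np.round(mb[:6], 3))
print("ROIs 0-5 carry the 1.8x medial stimulation amplitude; the rest ~1x.")

nets = ([residual_network(r, "ON") for r in runs]
        + [residual_network(r, "OFF") for r in runs])
z = np.mean([n.z for n in nets], axis=0)
on = np.mean([n.z for n in nets[:4]], axis=0)
off = np.mean([n.z for n in nets[4:]], axis=0)
iu = np.triu_indices(gt.n_roi, 1)
print(f"\nON/OFF network similarity (Pearson r of Fisher-z edges): "
      f"{np.corrcoef(on[iu], off[iu])[0, 1]:.2f} — background connectivity "
      f"is stable across stimulation state.")

membership = community_consensus(z, n_runs=200, seed=5)
sizes = [gt.n_roi // 3, gt.n_roi // 3, gt.n_roi - 2 * (gt.n_roi // 3)]
truth = np.concatenate([[k] * s for k, s in enumerate(sizes)])
print(f"consensus communities: {membership.tolist()}")
print(f"adjusted Rand index vs planted partition: "
      f"{adjusted_rand_score(truth, membership):.2f} (1.0 = exact recovery)")
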