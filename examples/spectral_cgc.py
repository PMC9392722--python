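"""Directed connectivity via nonparametric spectral conditional Granger
causality, validated against the generating model.

Simulates a three-channel chain system x -> y -> z, estimates the
cross-spectral matrix by multitaper averaging, factorizes it (Wilson), and
compares conditional GC with the phase-randomized surrogate threshold:
the direct links are significant, the mediated x -> z link is not.
"""

import numpy as np

from esconn.cgc import analyze_run
from esconn.synthetic import VarSpec, simulate_var, var_time_domain_gc

A = np.zeros((1, 3, 3))
A[0] = [[0.5, 0.0, 0.0],
        [0.6, 0.4, 0.0],
        [0.0, 0.6, 0.3]]
spec = VarSpec(A, np.eye(3))
trials = simulate_var(spec, n_trials=100, n_samples=2000, seed=2, fs=200.0)

res = analyze_run(trials, window_ms=(0, 10000), eval_freq_hz=8.0,
                  n_surr=60, seed=3, nfft=512)
names = list(res.channels["name"])
b = res.eval_bin
print(f"conditional GC at {res.freqs[b]:.2f} Hz "
      f"(threshold = 95% point of 60 phase-randomized surrogates):")
for s in range(3):
    for t in range(3):
        if s == t:
            continue
        oracle = var_time_domain_gc(spec, s, t,
                                    cond=[c for c in range(3)
                                          if c not in (s, t)])
        star = "*" if res.significant[s, t] else " "
        print(f"  {names[s]} -> {names[t]}: {res.cgc[s, t, b]:.4f} "
              f"(thr {res.threshold[s, t]:.4f}){star}  "
              f"[freq-mean {res.cgc[s, t].mean():.4f}, "
              f"parametric oracle {oracle:.4f}]")
print("\n* = exceeds the surrogate threshold at the evaluation frequency. "
      "The frequency-averaged spectral GC matches the parametric oracle "
      "(Geweke's integral identity); the mediated x -> z influence is "
      "conditioned away.")
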