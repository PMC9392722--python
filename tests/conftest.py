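"""Shared fixtures: small synthetic datasets reused across test modules.

Everything is generated programmatically with fixed seeds; sizes are kept
small enough for a quick default run while remaining statistically
meaningful for the calibration and recovery checks.
"""

import numpy as np
import pandas as pd
import pytest

from esconn.synthetic import (BoldGroundTruth, EpGroundTruth, GroupResponse,
                              VarSpec, default_bold_ground_truth,
                              default_channel_table, default_ep_ground_truth,
                              simulate_bold, simulate_ep_trials, simulate_var)


@pytest.fixture(scope="session")
def bivar_spec():
    """Bivariate VAR(2) with x(ch0) -> y(ch1) coupling only."""
    A = np.zeros((2, 2, 2))
    A[0] = [[0.55, 0.0], [0.45, 0.5]]
    A[1] = [[-0.8, 0.0], [0.0, -0.2]]
    return VarSpec(A, np.eye(2))


@pytest.fixture(scope="session")
def chain_spec():
    """Chain VAR(1): x -> y -> z, no direct x -> z link."""
    A = np.zeros((1, 3, 3))
    A[0] = [[0.5, 0, 0], [0.6, 0.4, 0], [0, 0.6, 0.3]]
    return VarSpec(A, np.eye(3))


@pytest.fixture(scope="session")
def bivar_trials(bivar_spec):
    return simulate_var(bivar_spec, n_trials=100, n_samples=2000, seed=3,
                        fs=200.0)


@pytest.fixture(scope="session")
def chain_trials(chain_spec):
    return simulate_var(chain_spec, n_trials=100, n_samples=2000, seed=5,
                        fs=200.0)


@pytest.fixture(scope="session")
def ep_run():
    """One lateral-stimulation run, two channels per ROI group, 5% artifacts."""
    gt = default_ep_ground_truth(artifact_rate=0.05)
    chan = default_channel_table(n_per_group=2)
    return simulate_ep_trials(gt, n_trials=60, fs=8000, seed=11,
                              stim_group="lateral", channels=chan)


@pytest.fixture(scope="session")
def noiseless_run():
    """Single-component noiseless EP: +8 SD bump at 15 ms, no late bump."""
    entries = {(g, s): GroupResponse(early_latency_ms=15.0,
                                     early_amplitude_sd=8.0,
                                     late_latency_ms=150.0,
                                     late_amplitude_sd=0.0)
               for g in ("OF", "lPFC", "SM", "PL", "TL", "CC")
               for s in ("medial", "lateral")}
    gt = EpGroundTruth(entries=entries)
    return simulate_ep_trials(gt, n_trials=5, fs=8000, seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def bold_gt():
    return default_bold_ground_truth()


@pytest.fixture(scope="session")
def bold_runs_medial(bold_gt):
    return simulate_bold(bold_gt, 6, seed=21, stim_group="medial")


@pytest.fixture(scope="session")
def noiseless_bold():
    gt = default_bold_ground_truth(noise_sd=0.0, motion_spike_prob=0.0)
    return simulate_bold(gt, 1, seed=1, response_in_basis=True)[0]
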