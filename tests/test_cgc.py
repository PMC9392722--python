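"""Spectral estimation, Wilson factorization and conditional Granger
causality, validated against parametric VAR oracles and surrogate nulls."""

import numpy as np
import pytest

from esconn.containers import SpectralMatrix
from esconn.cgc import (cgc_matrix, conditional_gc, estimate_csd,
                        pairwise_gc, phase_randomize, surrogate_threshold,
                        summarize_network, wilson_factorize)
from esconn.synthetic import (VarSpec, simulate_var, var_spectral_matrix,
                              var_time_domain_gc)


def _analytic_sm(spec, fs=200.0, nfft=512):
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return SpectralMatrix(S=var_spectral_matrix(spec, freqs, fs), freqs=freqs,
                          fs=fs)


@pytest.fixture(scope="module")
def white_trials():
    spec = VarSpec(np.zeros((1, 3, 3)), np.eye(3))
    return simulate_var(spec, n_trials=60, n_samples=512, seed=7, fs=200.0)


class TestEstimateCsd:
    def test_hermitian_to_machine_precision(self, white_trials):
        S = estimate_csd(white_trials, window_ms=(0, 2560))
        np.testing.assert_allclose(S.S, np.conj(np.swapaxes(S.S, 1, 2)),
                                   atol=1e-14)

    def test_white_noise_flat_auto_zero_cross(self, white_trials):
        S = estimate_csd(white_trials, window_ms=(0, 2560))
        auto = np.real(S.S[:, np.arange(3), np.arange(3)])
        # two-sided density of unit white noise at fs=200 is 1/200
        np.testing.assert_allclose(auto.mean(), 1 / 200, rtol=0.1)
        cross = S.S[:, 0, 1]
        assert np.abs(cross).mean() < 0.2 * auto.mean()

    def test_matches_analytic_var_spectrum(self, bivar_spec, bivar_trials):
        S = estimate_csd(bivar_trials, window_ms=(0, 10000))
        Sa = var_spectral_matrix(bivar_spec, S.freqs, bivar_trials.fs)
        rel = (np.linalg.norm(S.S - Sa, axis=(1, 2))
               / np.linalg.norm(Sa, axis=(1, 2)))
        assert np.median(rel) < 0.10
        assert rel.mean() < 0.12

    def test_too_few_trials_rejected(self, white_trials):
        one = simulate_var(VarSpec(np.zeros((1, 2, 2)), np.eye(2)), 1, 64,
                           seed=0)
        with pytest.raises(ValueError, match="trials"):
            estimate_csd(one, window_ms=(0, 320))


class TestWilsonFactorize:
    def test_scalar_constant_spectrum_closed_form(self):
        sigma2 = 2.5
        nfft = 64
        freqs = np.fft.rfftfreq(nfft)
        S = np.full((len(freqs), 1, 1), sigma2, dtype=complex)
        f = wilson_factorize(SpectralMatrix(S=S, freqs=freqs, fs=1.0))
        np.testing.assert_allclose(f.Sigma, [[sigma2]], rtol=1e-8)
        np.testing.assert_allclose(np.abs(f.H), 1.0, atol=1e-8)

    def test_reconstruction_invariant_on_smooth_spectrum(self, bivar_spec):
        S = _analytic_sm(bivar_spec)
        f = wilson_factorize(S)
        recon = f.H @ (f.Sigma / S.fs) @ np.conj(np.swapaxes(f.H, 1, 2))
        rel = (np.linalg.norm(recon - S.S, axis=(1, 2))
               / np.linalg.norm(S.S, axis=(1, 2)))
        assert rel.max() < 1e-6
        assert f.residual < 1e-6

    def test_innovation_covariance_recovered(self, bivar_spec):
        f = wilson_factorize(_analytic_sm(bivar_spec))
        np.testing.assert_allclose(f.Sigma, bivar_spec.noise_cov, rtol=0.01,
                                   atol=0.01)

    def test_estimated_spectrum_sigma_within_one_percent(self, bivar_trials,
                                                         bivar_spec):
        S = estimate_csd(bivar_trials, window_ms=(0, 10000))
        f = wilson_factorize(S)
        np.testing.assert_allclose(np.diag(f.Sigma),
                                   np.diag(bivar_spec.noise_cov), rtol=0.02)


class TestGrangerCausality:
    def test_independent_channels_near_zero(self, white_trials):
        S = estimate_csd(white_trials, window_ms=(0, 2560))
        res = cgc_matrix(S, channels=white_trials.channels)
        off = ~np.eye(3, dtype=bool)
        assert np.nanmax(res.cgc[off]) < 0.05

    def test_spectral_mean_matches_time_domain_oracle(self, bivar_spec,
                                                      bivar_trials):
        """Geweke integral identity: the frequency average of spectral GC on
        the full circle equals the time-domain value, within 10%."""
        F = var_time_domain_gc(bivar_spec, 0, 1)
        S = estimate_csd(bivar_trials, window_ms=(0, 10000))
        g = pairwise_gc(S, 0, 1)
        assert g.mean() == pytest.approx(F, rel=0.10)

    def test_uncoupled_direction_small(self, bivar_trials):
        S = estimate_csd(bivar_trials, window_ms=(0, 10000))
        assert pairwise_gc(S, 1, 0).mean() < 0.02

    def test_chain_conditional_vs_pairwise(self, chain_spec, chain_trials):
        """x->y->z: conditional x->z|y vanishes, pairwise x->z does not."""
        S = estimate_csd(chain_trials, window_ms=(0, 10000))
        cond = conditional_gc(S, 0, 2)
        pair = pairwise_gc(S, 0, 2)
        F_pair = var_time_domain_gc(chain_spec, 0, 2)
        assert cond.mean() < 0.02
        assert pair.mean() == pytest.approx(F_pair, rel=0.15)
        assert pair.mean() > 5 * cond.mean()

    def test_conditional_matches_oracle_on_coupled_edges(self, chain_spec,
                                                         chain_trials):
        S = estimate_csd(chain_trials, window_ms=(0, 10000))
        for s, t in [(0, 1), (1, 2)]:
            F = var_time_domain_gc(chain_spec, s, t,
                                   cond=[c for c in range(3) if c not in (s, t)])
            assert conditional_gc(S, s, t).mean() == pytest.approx(F, rel=0.10)

    def test_nonnegative_and_diag_nan(self, chain_trials):
        S = estimate_csd(chain_trials, window_ms=(0, 2000))
        res = cgc_matrix(S, channels=chain_trials.channels)
        assert np.isnan(res.cgc[np.arange(3), np.arange(3)]).all()
        assert np.nanmin(res.cgc) >= 0.0

    def test_permutation_equivariance(self, chain_spec):
        """Relabelling channels permutes the CGC matrix accordingly."""
        S = _analytic_sm(chain_spec, nfft=128)
        res = cgc_matrix(S)
        perm = [2, 0, 1]
        Sp = SpectralMatrix(S=S.S[:, perm][:, :, perm], freqs=S.freqs, fs=S.fs)
        resp = cgc_matrix(Sp)
        np.testing.assert_allclose(resp.cgc,
                                   res.cgc[perm][:, perm], rtol=1e-4,
                                   atol=1e-6)

    def test_source_equals_target_rejected(self, chain_trials):
        S = estimate_csd(chain_trials, window_ms=(0, 2000))
        with pytest.raises(ValueError, match="differ"):
            conditional_gc(S, 1, 1)


class TestSurrogates:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 128))
        y = phase_randomize(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(y, axis=-1)),
                                   np.abs(np.fft.rfft(x, axis=-1)),
                                   rtol=1e-10, atol=1e-10)
        assert np.iscomplexobj(y) is False

    def test_seed_reproducibility(self, white_trials):
        kw = dict(window_ms=(0, 1280), n_surr=20, seed=4, nfft=256)
        a = surrogate_threshold(white_trials, **kw)
        b = surrogate_threshold(white_trials, **kw)
        np.testing.assert_array_equal(a, b)

    def test_null_exceedance_near_five_percent(self):
        """True CGC of independent channels exceeds the per-dataset surrogate
        threshold at the evaluation bin ~5% of the time."""
        spec = VarSpec(np.zeros((1, 2, 2)), np.eye(2))
        hits = trials_n = 0
        for seed in range(12):
            ts = simulate_var(spec, n_trials=30, n_samples=256, seed=100 + seed,
                              fs=200.0)
            S = estimate_csd(ts, window_ms=(0, 1280), nfft=256)
            res = cgc_matrix(S, channels=ts.channels)
            thr = surrogate_threshold(ts, window_ms=(0, 1280), n_surr=40,
                                      seed=seed, nfft=256)
            b = int(np.argmin(np.abs(S.freqs - 8.0)))
            for s, t in [(0, 1), (1, 0)]:
                hits += res.cgc[s, t, b] > thr[s, t, b]
                trials_n += 1
        assert hits / trials_n <= 0.25   # 24 draws: binomial(24, .05) upper tail


class TestNetworkSummary:
    def test_uniform_cgc_degree_arithmetic(self):
        """All-significant uniform CGC c over k groups: in-degree (k-1) c."""
        import pandas as pd

        k, nf, c = 4, 9, 0.3
        cgc = np.full((k, k, nf), c)
        cgc[np.arange(k), np.arange(k)] = np.nan
        chan = pd.DataFrame(dict(name=[f"c{i}" for i in range(k)],
                                 roi=list("ABCD"), roi_group=list("ABCD"),
                                 hemisphere="R", in_soz=False,
                                 in_white_matter=False))
        from esconn.containers import SpectralCGCResult
        res = SpectralCGCResult(cgc=cgc, freqs=np.linspace(0, 40, nf),
                                channels=chan,
                                threshold=np.zeros((k, k)), eval_freq_hz=8.0,
                                eval_bin=2)
        out = summarize_network(res, eval_freq_hz=8.0)
        np.testing.assert_allclose(out["in_degree"], (k - 1) * c)
        np.testing.assert_allclose(out["out_degree"], (k - 1) * c)

    def test_eval_freq_snaps_to_nearest_bin(self, chain_trials):
        S = estimate_csd(chain_trials, window_ms=(0, 2000), nfft=256)
        res = cgc_matrix(S, channels=chain_trials.channels)
        res.threshold = np.zeros((3, 3))
        res.eval_bin = 0
        out = summarize_network(res, eval_freq_hz=8.3)
        expected = S.freqs[np.argmin(np.abs(S.freqs - 8.3))]
        assert out["eval_freq_hz"] == pytest.approx(expected)
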