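# Methods

This note documents the models, estimators, defaults and numerical choices
behind `esconn`, and what the synthetic-data validation does and does not
establish.

## Evoked-potential model and quantification

**Trial model.** A stimulation-locked trial on channel *c* is
`x_c(t) = s_c(t) + n_c(t)` on [−1000, +1000] ms around onset. The evoked
part `s_c` is the sum of two Gaussian bumps: an early component (latency
10–30 ms, signed amplitude — its sign sets N vs P polarity; width σ = 4 ms)
and a late, non-negative component (latency 70–200 ms, σ = 40 ms). The
background `n_c` is Gaussian 1/f^α noise (α = 1 by default), independent
across trials. Real CCEPs are not Gaussian bumps; the shapes were chosen as
smooth, unimodal and with unambiguous peaks so that latency recovery has a
well-defined target. Artifact trials occur at a configurable rate and take
one of the two forms the rejection stage is built for: a large spike
(80 × noise SD) or a saturation plateau (60 × noise SD for 50 ms).

**Amplitude convention.** Ground-truth amplitudes are expressed in units of
the expected baseline SD of the *averaged* EP: the generator scales bump
volts by `noise_sd / √n_trials`, so after averaging and baseline
normalization the recovered peak approximates the injected number. With
`noise_sd = 0` traces are emitted directly in those units and normalization
becomes a flagged no-op (the only coherent reading of a "noiseless EP in SD
units").

**Rejection.** Per trial, baseline SD is computed over [−100, −10) ms; a
trial is discarded if |x| > 10 SD at 8 ms (stimulus-artifact tail) or
|x| > 50 SD anywhere in [8, 1000] ms. Channels in the seizure-onset zone or
white matter are excluded wholesale. A zero baseline SD disables the rules
for that channel and is flagged, never silently passed.

**Windows and mapping.** All windows are half-open `[a, b)` in ms with
time 0 at stimulation onset and sample index `floor(fs · t)`. Early
features (range, latency, polarity, trend) are measured on the band-passed
trace; the filter is a 2nd-order Butterworth 2–200 Hz applied
forward–backward, so the composed response is −6.02 dB at each cutoff. The
late component is the largest positive local peak of the raw normalized
trace in [70, 200) ms. "Earliest peak" means the first local extremum
(either sign) with prominence ≥ 1 SD; ties break to the earlier sample.
Channels without a qualifying extremum get polarity `absent` and are
excluded from latency statistics. Latency for the early window is measured
on the same filtered trace used for its range, for internal consistency;
the late latency uses the unfiltered trace.

**Significance.** The null for a window of length L is built by tiling
[−1000, −10) ms with L-length windows at a 10 ms step and pooling their
range values; the threshold is the pool's 95th percentile computed with the
`higher` order statistic. With ~100 pooled (overlapping) windows the
interpolated quantile sits low and the test over-fires (~6.4% empirically);
the `higher` estimator restores the exceedance probability to ~5%. Residual
mis-calibration from window overlap is below 1 percentage point and is
covered by the Monte-Carlo tolerance of the calibration checks.

**Group statistics.** Per-ROI medial/lateral contrasts are two-sided
two-sample t-tests on range values, Bonferroni-corrected by the number of
testable ROIs. Latency group structure uses one-way ANOVA with Tukey HSD
post hoc tests. The sex/hemisphere descriptive mode reports only effect
sizes (mean difference ± SE) by design.

## Stimulation-site decoding

The classifier contract is a gradient-boosted decision-tree ensemble with
native categorical support; the implementation is scikit-learn's
histogram-based gradient boosting configured to that contract
(depth 14, 200 iterations, log-loss, learning rate 0.03). Features enter in
the declared order `range_early, range_late, lat_early, lat_late, roi,
trend_early, trend_late`. Cross-validation is 10-fold; by default folds are
grouped by run (channels within a run share the stimulus and would
otherwise leak across folds) with a `none` mode available, since the
original protocol does not state the grouping. Waveform decoding reduces
the time axis with UMAP (n_neighbors 15, min_dist 0.1, Euclidean, seed 1234
recorded in the result) to 2–100 components. Latency-group maps fit the
same classifier on the 2-D embedding and evaluate it on a 400 × 400 grid
spanning the bounding box plus a 5% margin; per-group accuracy is the
fraction of that group's points classified correctly.

## Nonparametric spectral conditional Granger causality

**Spectral estimation.** The 70–200 ms epoch (130 ms, 1040 samples at
8 kHz) is demeaned per channel and trial and tapered with 3 unit-energy
Slepian windows (time–bandwidth 2). The FFT length defaults to the next
power of two above the window length — 2048 at 8 kHz, giving a ~3.9 Hz grid
with nearest-bin selection for the 8 Hz evaluation frequency. (A fixed
512-sample pad would truncate the native window, so the padding rule is
length-relative.) The estimate is the two-sided density
`S(f) = ⟨X X*⟩ / (K · M · fs)` averaged over K tapers and M trials.

**Factorization.** Wilson's iterative algorithm factorizes
`S(f) = H(f) (Σ/fs) H*(f)` with minimum-phase `H` and innovation
covariance `Σ`. On analytic (smooth) spectra the iteration converges to
machine precision and the reconstruction invariant holds below 1e-6. On
*estimated* spectra the iteration bottoms out at a floor of order
1/√(n_tapers · n_trials): the minimum-phase factor of a noisy spectrum
needs lags beyond the half-circle truncation that defines the discrete
factorization. The implementation detects this plateau (ten consecutive
non-decreasing update steps), returns with iteration/residual diagnostics,
and raises only when the residual exceeds 5% — a genuine failure.
Empirically the Granger values computed from a stalled-at-noise-floor
factorization agree with parametric oracles to ~1%. Rank-deficient spectra
receive diagonal loading `1e-8 · trace(S)/ch` before iteration.

**Conditional GC.** Causality from source *s* to target *t* given the
remaining channels uses two factorizations — the full system and the system
with *s* removed (transfer `G`, innovations `Σ_R`). The reduced transfer is
embedded with an identity row at the source, the full-system innovations
are linearly transformed so the target's innovation is uncorrelated with
the rest, and
`f_{s→t|rest}(f) = ln(Σ_R,tt / |Q_tt(f)|² Σ_tt)` with
`Q = G_ext⁻¹ H L⁻¹`. With an empty conditioning set this reduces exactly to
Geweke's pairwise spectral measure. One full factorization plus one per
source channel covers all directed pairs. Negative values from numerical
round-off are clipped at zero.

**Oracles.** Two independent routes validate the estimator: (i) the
time-domain Geweke value computed from the generating VAR coefficients via
analytic autocovariances (spectral route) and multivariate Yule–Walker
equations of order 64 — no spectral factorization involved; (ii) the
Geweke integral identity, `mean_f f(f) = F_time-domain`, checked to 10% on
100 trials × 2000 samples.

**Surrogates.** Phase randomization acts per trial and channel on the
epoch: Fourier phases of non-DC, non-Nyquist bins are replaced by iid
uniform draws with conjugate symmetry, preserving each amplitude spectrum
exactly while destroying cross-channel phase relations. The procedure
recomputes the full CGC pipeline per surrogate; the threshold is the 95th
percentile over iterations (200 by default; 40–60 in the validation
experiments, which is ample for a 95% point), averaged
over runs when several runs are analyzed. Type-I error of the procedure
calibrates at ~5% on independent channels.

## BOLD pipeline

**Generator.** A run is `baseline + a_i · (block ⊛ h)(t) + ε(t)` per ROI,
with 10-frame ON / 10-frame OFF cycles at TR = 3 s, a double-gamma kernel
`h` (peak-normalized), noise `ε ~ N(0, Ω⁻¹)` from a ground-truth precision
matrix `Ω`, and motion spikes that appear both in the FD trace (+1.5 mm)
and as signal glitches. The default `Ω` plants three equal communities
(partial correlation 0.12 within, 0 between); medial and lateral amplitude
vectors differ in which community carries the 1.8× response. With
`response_in_basis=True` the per-block response is replaced by its exact
representation in the deconvolution basis, creating the regime where
least-squares deconvolution must be exact.

**Deconvolution.** Each ROI series is scaled to mean 100 (betas are in
percent-signal units — this couples amplitude into the scale at the ~1%
level, visible as a mean-beta ratio of 1.99 rather than 2.00 in the
linearity check). The design holds 14 shared response columns — the
cardinal natural-cubic-spline basis on knots −3, 0, …, 36 s evaluated at
each frame's lag from every onset — plus intercept, linear drift and
nuisance columns. Frames with FD > 0.9 mm, the frame before each, and the
first two frames of the run are censored from the fit; residuals are formed
on all frames. Rank deficiency after censoring raises an error naming the
collinear columns. Plain least squares is used; the voxel-wise
ARMA-prewhitened fit of the original pipeline has no ROI-level analogue
here and temporal autocorrelation mainly affects standard errors, which
this stage does not report. Mean beta is the average of the reconstructed
spline response on a 1 s grid over 3–30 s; dropout ROIs propagate NaN.

**Residual networks.** The nominal 0.1–1 Hz band-pass exceeds the Nyquist
frequency of TR = 3 s data (0.167 Hz); the only physically realizable
reading — a 0.1 Hz high-pass with the upper edge clipped — is applied, with
a loud (once-per-session) warning, and both edges remain configurable.
ON/OFF frame labels are shifted by one TR for hemodynamic delay
(configurable). Partial correlations come from the inverse of a
Ledoit–Wolf-shrunk covariance by default — with 19 ROIs and a few dozen
frames per condition the sample covariance is ill-conditioned — and are
Fisher-z transformed. Contrasts are edge-wise two-sided t-tests
(two-sample by default; a paired option exists for ON/OFF within runs)
under Benjamini–Hochberg FDR at 0.05.

**Communities.** The positive part of the network is clustered by Leiden
modularity (RB configuration, resolution 1.0) in 200 seeded runs; the
co-assignment frequency matrix is thresholded at 0.5 and reclustered once
for the consensus membership. Empty graphs yield singleton communities.

**Run classification.** Mean-beta tables are classified medial vs lateral
by bagged decision trees (250 trees, per-split √p feature sampling).
Class imbalance is handled by SMOTE — synthetic minority samples on
segments toward one of 5 nearest minority neighbours — applied *inside each
bootstrap bag*, so out-of-bag predictions are leak-free by construction: a
synthetic sample can never derive from a run that is out of bag for its
tree. (Balancing once before fitting, then reading the out-of-bag score,
inflates the shuffled-label AUC to ~0.7 through parent–child leakage; the
in-bag variant calibrates it at chance.) Importances are impurity-based,
averaged over trees; the significance threshold is mean + 5 SD of
importances over 100 label-shuffled re-runs. Dropout ROIs are
median-imputed within class with missingness indicator columns.

## Validation experiments and their limits

`esconn.validation` runs each end-to-end check at fixed problem sizes
chosen to keep the default run a few minutes on one core: the Granger
oracle at 100 trials × 2000 samples; null calibrations on 1000 noise
channels (EP), 25 two-channel datasets × 60 surrogates (CGC), and 4 × 8
null runs (FDR); recovery from 2 runs × 36 channels (latency), 4 runs × 40
block cycles (communities), and 16 runs × 24 channels (decoding). The
acceptance script (`scripts/acceptance.py`) reports these numbers as JSON;
the test suite asserts them at their tolerances.

What passing shows: the estimators are algebraically correct (oracle
equivalence, exactness, linearity), their significance procedures are
calibrated on their own null models, and the pipeline recovers planted
structure at realistic SNR. What it does not show: robustness to real
iEEG/fMRI nuisance structure — epileptiform morphology, volume conduction,
electrode drift, physiological noise, scanner artifacts — none of which the
generators emulate, nor any patient-level result, which requires real
recordings. Latency defaults in the generator follow representative human
CCEP group means (orbitofrontal and cingulate earliest, parietal latest,
~17–21 ms early and ~129–157 ms late) so that recovery targets that
ordering; amplitudes encode the medial/lateral asymmetry (early larger
under lateral, late larger under medial stimulation) with an SNR fixed once
at 8 vs 5 SD.

## Seeds and determinism

Every generator and every stochastic analysis stage takes an explicit seed;
one master seed spawns per-stage seeds below 2³¹ (`esconn.io.spawn_seeds`),
and containers record the seed that produced them. Identical seeds give
bit-identical outputs end to end (hash-checked in the tests). The UMAP
embedding seed defaults to 1234 and is stored in the result.
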