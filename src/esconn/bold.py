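"""ROI-level analysis of block-design stimulation fMRI runs.

First-order stage: flexible-shape (FIR-style) deconvolution of the BOLD
response with a 14-knot natural-cubic-spline basis spanning -3 to 36 s
around each stimulation-block onset, after per-ROI scaling to mean 100,
with motion censoring (frames with FD > 0.9 mm and the frame before) and
nuisance regressors; mean beta over 3-30 s summarizes each ROI's response.

Second-order stage: "background connectivity" — partial correlations among
ROI residual series (high-pass filtered, ON and OFF frames pooled
separately), Fisher-z transformed, contrasted across conditions with
edge-wise t-tests under Benjamini-Hochberg FDR, clustered into communities
by seeded Leiden runs with consensus reclustering, and fed (as mean betas)
to a SMOTE-balanced random-forest run classifier with shuffled-label
importance thresholds.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .containers import BoldRun, PartialCorrNetwork
from .splines import cardinal_spline_basis

FD_CENSOR_MM = 0.9
DISCARD_FRAMES = 2
KNOT_WINDOW_S = (-3.0, 36.0)
N_BASIS = 14
MEAN_BETA_S = (3.0, 30.0)


# ---------------------------------------------------------------------------
# censoring and deconvolution
# ---------------------------------------------------------------------------

def censor_mask(run: BoldRun, fd_thresh: float = FD_CENSOR_MM,
                discard_first: int = DISCARD_FRAMES) -> np.ndarray:
    """Usable-frame mask: drop the first frames, high-motion frames
    (FD > 0.9 mm) and the frame preceding each of them."""
    bad = run.fd > fd_thresh
    bad[:-1] |= bad[1:]                  # censor the frame before a spike
    mask = ~bad
    mask[:discard_first] = False
    return mask


def design_matrix(run: BoldRun, nuisance: Optional[np.ndarray] = None):
    """Spline response basis per block onset plus intercept/drift/nuisance.

    Response columns are shared across blocks (one coefficient per knot):
    column j accumulates the cardinal natural-spline basis function of knot
    j evaluated at each frame's lag from every onset.  Returns
    ``(X, n_response_columns)``.
    """
    t = np.arange(run.n_frames) * run.tr
    knots = np.linspace(KNOT_WINDOW_S[0], KNOT_WINDOW_S[1], N_BASIS)
    resp = np.zeros((run.n_frames, N_BASIS))
    for o in run.onsets:
        resp += cardinal_spline_basis(knots, t - o * run.tr)
    drift = (t - t.mean()) / t.std()
    cols = [resp, np.ones((run.n_frames, 1)), drift[:, None]]
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != run.n_frames:
            nuis = nuis.T
        cols.append(nuis)
    return np.column_stack(cols), N_BASIS


def fir_deconvolve(run: BoldRun, nuisance: Optional[np.ndarray] = None,
                   fd_thresh: float = FD_CENSOR_MM) -> BoldRun:
    """Least-squares flexible-shape deconvolution of one run.

    Each ROI series is scaled to mean 100, fitted on censored frames with
    the spline response basis plus intercept, linear drift and any nuisance
    columns; betas (one per knot, in percent-signal units) and full-model
    residuals (on *all* frames) are attached to the returned run.
    """
    mask = censor_mask(run, fd_thresh=fd_thresh)
    X, nb = design_matrix(run, nuisance=nuisance)
    Xm = X[mask]
    rank = np.linalg.matrix_rank(Xm)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        _, R = np.linalg.qr(Xm)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max())
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient after censoring "
            f"(collinear columns: {bad.tolist()})")
    scale = run.series.mean(axis=1, keepdims=True)
    if np.any(scale <= 0):
        raise ValueError("non-positive mean signal; cannot scale to mean 100")
    Y = run.series / scale * 100.0
    beta_all, *_ = np.linalg.lstsq(Xm, Y[:, mask].T, rcond=None)
    fitted = X @ beta_all
    out = BoldRun(series=run.series, roi_names=run.roi_names, tr=run.tr,
                  onsets=run.onsets, frames_on=run.frames_on,
                  frames_off=run.frames_off, fd=run.fd,
                  stim_group=run.stim_group, run_id=run.run_id, seed=run.seed,
                  ground_truth=run.ground_truth)
    out.betas = beta_all[:nb].T.copy()
    out.residuals = (Y - fitted.T)
    out.censor_mask = mask
    return out


def mean_beta(run: BoldRun, interval_s: tuple = MEAN_BETA_S,
              grid_step_s: float = 1.0) -> np.ndarray:
    """Per-ROI mean of the spline-reconstructed response over 3-30 s.

    The fitted response shape (sum of basis columns weighted by betas) is
    evaluated on a regular grid over the interval and averaged.  ROIs whose
    betas are missing (signal dropout) yield NaN, which is propagated.
    """
    if run.betas is None:
        raise ValueError("run has no betas; call fir_deconvolve first")
    if not (KNOT_WINDOW_S[0] <= interval_s[0] < interval_s[1] <= KNOT_WINDOW_S[1]):
        raise ValueError("interval must lie within the basis window")
    knots = np.linspace(KNOT_WINDOW_S[0], KNOT_WINDOW_S[1], N_BASIS)
    grid = np.arange(interval_s[0], interval_s[1] + 1e-9, grid_step_s)
    B = cardinal_spline_basis(knots, grid)
    return (run.betas @ B.T).mean(axis=1)


# ---------------------------------------------------------------------------
# residual (background) partial-correlation networks
# ---------------------------------------------------------------------------

def condition_frames(run: BoldRun, condition: str, hrf_shift_frames: int = 1,
                     mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Frame indices belonging to the stimulation ON or OFF condition.

    Block labels are shifted by ``hrf_shift_frames`` TRs to allow for
    hemodynamic delay before a frame is attributed to a condition.
    """
    on = np.zeros(run.n_frames, dtype=bool)
    for o in run.onsets:
        a = o + hrf_shift_frames
        on[a:a + run.frames_on] = True
    sel = on if condition.upper() == "ON" else ~on
    if condition.lower() == "all":
        sel = np.ones(run.n_frames, dtype=bool)
    if mask is not None:
        sel = sel & mask
    return np.flatnonzero(sel)


def _highpass(x: np.ndarray, tr: float, low_hz: float = 0.1,
              high_hz: float = 1.0) -> np.ndarray:
    """Band-pass residual series; the upper edge is clipped to Nyquist.

    With TR = 3 s the Nyquist frequency (0.167 Hz) is below the nominal 1 Hz
    upper edge, so the filter degenerates to a 0.1 Hz high-pass (warned)."""
    nyq = 0.5 / tr
    if high_hz >= nyq:
        if not _highpass._warned:
            warnings.warn(
                f"band-pass upper edge {high_hz} Hz is above Nyquist "
                f"{nyq:.3f} Hz for TR={tr}s; applying a {low_hz} Hz high-pass "
                f"only (further occurrences suppressed)")
            _highpass._warned = True
        sos = sps.butter(2, low_hz, btype="highpass", fs=1.0 / tr, output="sos")
    else:
        sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr,
                         output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


_highpass._warned = False


def partial_correlation(frames: np.ndarray, shrinkage: bool = True) -> np.ndarray:
    """Partial correlations from the (optionally Ledoit-Wolf shrunk) inverse
    covariance of ``frames`` (observations x variables)."""
    n, k = frames.shape
    if shrinkage or n < k + 2:
        cov = LedoitWolf(assume_centered=False).fit(frames).covariance_
    else:
        cov = np.cov(frames.T)
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def residual_network(run: BoldRun, condition: str = "ON",
                     shrinkage: bool = True, hrf_shift_frames: int = 1,
                     filter_band: tuple = (0.1, 1.0)) -> PartialCorrNetwork:
    """Fisher-z partial-correlation network of residual series, per condition.

    Residuals are high-pass filtered, the frames of the requested condition
    (surviving the censor mask) are concatenated across blocks, and partial
    correlations are computed from the inverse (shrunk) covariance.
    """
    if run.residuals is None:
        raise ValueError("run has no residuals; call fir_deconvolve first")
    filt = _highpass(run.residuals, run.tr, *filter_band)
    idx = condition_frames(run, condition, hrf_shift_frames, run.censor_mask)
    if idx.size < 3:
        raise ValueError(f"only {idx.size} usable {condition} frames")
    pc = partial_correlation(filt[:, idx].T, shrinkage=shrinkage)
    z = np.arctanh(np.clip(pc, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    return PartialCorrNetwork(z=z, roi_names=run.roi_names,
                              condition=condition.upper(), run_id=run.run_id,
                              stim_group=run.stim_group, n_frames_used=idx.size)


def edge_contrast(networks_a: Sequence[PartialCorrNetwork],
                  networks_b: Sequence[PartialCorrNetwork],
                  alpha: float = 0.05, paired: bool = False) -> pd.DataFrame:
    """Edge-wise two-sided t contrast between two sets of networks.

    Fisher-z values per edge are compared across runs (two-sample by
    default, paired optional); Benjamini-Hochberg FDR is applied across all
    edges.  Returns a signed edge list with t, p, q and a significance flag.
    """
    if len(networks_a) < 2 or len(networks_b) < 2:
        raise ValueError("need at least two networks per level")
    roi = networks_a[0].roi_names
    k = len(roi)
    A = np.stack([n.z for n in networks_a])
    B = np.stack([n.z for n in networks_b])
    iu = np.triu_indices(k, 1)
    a, b = A[:, iu[0], iu[1]], B[:, iu[0], iu[1]]
    if paired:
        t, p = spstats.ttest_rel(a, b, axis=0)
    else:
        t, p = spstats.ttest_ind(a, b, axis=0)
    rej, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(dict(
        roi_a=[roi[i] for i in iu[0]], roi_b=[roi[j] for j in iu[1]],
        mean_diff=a.mean(axis=0) - b.mean(axis=0), t=t, p=p, q=q,
        significant=rej))


# ---------------------------------------------------------------------------
# consensus community detection
# ---------------------------------------------------------------------------

def _leiden_once(W: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    W = 0.5 * (W + W.T)            # igraph requires exact symmetry
    g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected", loops=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


def community_consensus(network: PartialCorrNetwork | np.ndarray,
                        resolution: float = 1.0, n_runs: int = 200,
                        seed: int = 0, co_thresh: float = 0.5) -> np.ndarray:
    """Consensus Leiden communities of a non-negative weighted network.

    Runs seeded Leiden modularity optimization ``n_runs`` times, forms the
    node-by-node co-assignment frequency matrix, thresholds it at 0.5 and
    reclusters the consensus graph once.  Negative edges are set to zero
    (the positive-correlation network; the negative network is analyzed
    separately).  An empty graph leaves every node in its own community.
    """
    W = network.z if isinstance(network, PartialCorrNetwork) else np.asarray(network)
    W = np.where(W > 0, W, 0.0)
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    if not W.any():
        return np.arange(n)
    co = np.zeros((n, n))
    for r in range(n_runs):
        m = _leiden_once(W, resolution, seed + r)
        co += (m[:, None] == m[None, :])
    co /= n_runs
    co = np.where(co >= co_thresh, co, 0.0)
    np.fill_diagonal(co, 0.0)
    return _leiden_once(co, resolution, seed + n_runs)


# ---------------------------------------------------------------------------
# run classification from mean betas
# ---------------------------------------------------------------------------

def smote(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
          seed: int = 0, return_parents: bool = False):
    """Synthetic minority oversampling: new minority samples are drawn on
    segments between a minority sample and one of its k nearest minority
    neighbours, until the classes are exactly balanced.

    With ``return_parents`` also returns, for each synthetic row, the indices
    (into ``X``) of the two originals it interpolates — needed downstream to
    keep out-of-bag estimates honest.
    """
    from sklearn.neighbors import NearestNeighbors

    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here supports two classes")
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(y == minority)
    if need == 0:
        out = (X.copy(), y.copy())
        return out + (np.empty((0, 2), dtype=int),) if return_parents else out
    Xm = X[min_idx]
    k = min(k_neighbors, len(Xm) - 1)
    if k < 1:
        raise ValueError("minority class too small for SMOTE")
    if k < k_neighbors:
        warnings.warn(f"reducing SMOTE neighbours to {k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    new = np.empty((need, X.shape[1]))
    parents = np.empty((need, 2), dtype=int)
    for i in range(need):
        a = rng.integers(len(Xm))
        b = idx[a][1 + rng.integers(k)]
        lam = rng.random()
        new[i] = Xm[a] + lam * (Xm[b] - Xm[a])
        parents[i] = (min_idx[a], min_idx[b])
    X_out = np.vstack([X, new])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    if return_parents:
        return X_out, y_out, parents
    return X_out, y_out


def _impute_by_class(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Median imputation within class for dropout ROIs, with indicator columns."""
    X = X.copy()
    has_nan = np.isnan(X).any(axis=0)
    indicators = np.isnan(X[:, has_nan]).astype(float)
    for c in np.unique(y):
        sel = y == c
        med = np.nanmedian(X[sel], axis=0)
        ii, jj = np.nonzero(np.isnan(X[sel]))
        X[np.flatnonzero(sel)[ii], jj] = med[jj]
    if indicators.size:
        X = np.column_stack([X, indicators])
    return X


def run_classification(mean_betas: np.ndarray, labels: Sequence[str],
                       feature_names: Optional[Sequence[str]] = None,
                       n_trees: int = 250, n_shuffles: int = 100,
                       importance_sd_factor: float = 5.0, seed: int = 0) -> dict:
    """SMOTE-balanced random-forest classification of runs (medial vs
    lateral stimulation) from per-ROI mean betas.

    Reports out-of-bag AUC for the actual labels and for ``n_shuffles``
    label-shuffled datasets, per-ROI importances, and the ROIs whose
    importance exceeds the shuffled mean + 5 SD threshold.

    The forest is bagged decision trees with per-split feature subsampling;
    SMOTE runs *inside* each bootstrap (the bag is balanced from its own
    members only), so out-of-bag predictions are leak-free by construction —
    a synthetic sample can never be interpolated from a run that is out of
    bag for that tree.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.tree import DecisionTreeClassifier

    X = np.asarray(mean_betas, dtype=float)
    y = np.asarray(list(labels))
    if min(np.unique(y, return_counts=True)[1]) < 3:
        raise ValueError("need at least 3 runs per class")
    if feature_names is None:
        feature_names = [f"roi{i}" for i in range(X.shape[1])]
    X = _impute_by_class(X, y)
    rng = np.random.default_rng(seed)

    def oob_fit(Xa, ya, rs):
        n = len(ya)
        pos_label = sorted(set(ya))[-1]
        local = np.random.default_rng(rs)
        votes = np.zeros(n)
        counts = np.zeros(n)
        imp_acc = np.zeros(Xa.shape[1])
        for t in range(n_trees):
            bag = local.integers(0, n, n)
            if len(np.unique(ya[bag])) < 2:
                continue
            if min(np.unique(ya[bag], return_counts=True)[1]) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    Xb_, yb_ = smote(Xa[bag], ya[bag],
                                     seed=int(local.integers(2 ** 31)))
            else:                       # bag too lopsided to interpolate
                Xb_, yb_ = Xa[bag], ya[bag]
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(local.integers(2 ** 31)))
            tree.fit(Xb_, yb_)
            imp_acc += tree.feature_importances_
            oob = np.setdiff1d(np.arange(n), bag)
            if oob.size:
                pos = list(tree.classes_).index(pos_label)
                votes[oob] += tree.predict_proba(Xa[oob])[:, pos]
                counts[oob] += 1
        ok = counts > 0
        prob = votes[ok] / counts[ok]
        auc = roc_auc_score((ya[ok] == pos_label).astype(int), prob)
        return float(auc), imp_acc / n_trees

    auc, imp = oob_fit(X, y, seed)
    sh_auc = np.empty(n_shuffles)
    sh_imp = np.empty((n_shuffles, imp.size))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        sh_auc[s], sh_imp[s] = oob_fit(X, ys, seed + 1 + s)
    thr = sh_imp.mean(axis=0) + importance_sd_factor * sh_imp.std(axis=0)
    n_real = len(feature_names)
    significant = [feature_names[i] for i in range(n_real) if imp[i] > thr[i]]
    return dict(oob_auc=auc, shuffled_auc=sh_auc, importances=imp[:n_real],
                importance_threshold=thr[:n_real],
                significant_rois=significant, feature_names=list(feature_names))
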