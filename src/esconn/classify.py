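"""Decoding the stimulated amygdala subdivision from evoked-potential data.

Two complementary decoders predict the stimulation site (medial vs lateral
group) from each recording contact's response: one from quantified EP
features (ranges, latencies, trend values, ROI identity as a categorical),
with features added sequentially to trace an accuracy curve; one from the
raw EP waveform after nonlinear dimensionality reduction of the time axis
(UMAP, 2-100 components).  A third analysis maps latency-defined groupings
(frontal / parietal+sensorimotor / temporal) in the 2-D embedding by
evaluating classifier decisions on a dense grid.

The classifier is a gradient-boosted decision-tree ensemble with native
categorical-feature support (tree depth 14, 200 boosting iterations,
log-loss, learning rate 0.03), evaluated with 10-fold cross-validation; the
identical protocol on label-shuffled copies provides the chance floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold

#: Declared order in which EP features enter the sequential analysis.
FEATURE_ORDER = ("range_early", "range_late", "lat_early", "lat_late",
                 "roi", "trend_early", "trend_late")

#: Latency-based groupings of the six anatomical ROI groups.
LATENCY_GROUPS = {"OF": "frontal", "lPFC": "frontal", "CC": "frontal",
                  "PL": "parietal_sm", "SM": "parietal_sm", "TL": "temporal"}


def make_classifier(seed: int = 0) -> HistGradientBoostingClassifier:
    """Gradient-boosted trees mirroring the depth-14 / 200-iteration /
    log-loss / lr-0.03 configuration, with native categorical handling."""
    return HistGradientBoostingClassifier(
        max_depth=14, max_iter=200, learning_rate=0.03,
        categorical_features="from_dtype", random_state=seed)


def feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-channel-per-window EP features into one decoding row per
    channel: range/latency/trend for both windows, ROI as a categorical, the
    stimulation-site label, and the run id (for grouped cross-validation)."""
    wide_rows = []
    for (run, ch), sub in features.groupby(["run_id", "channel"]):
        by_w = {r["window"]: r for _, r in sub.iterrows()}
        if "early" not in by_w or "late" not in by_w:
            continue
        e, l = by_w["early"], by_w["late"]
        if not (e.get("valid", True) and l.get("valid", True)):
            continue
        wide_rows.append(dict(
            run_id=run, channel=ch, roi=e["roi"],
            range_early=e["range_value"], range_late=l["range_value"],
            lat_early=e["peak_latency_ms"], lat_late=l["peak_latency_ms"],
            trend_early=e["trend_value"], trend_late=l["trend_value"],
            stim_group=e["stim_group"]))
    out = pd.DataFrame(wide_rows)
    if len(out):
        out["roi"] = out["roi"].astype("category")
    return out


def _cv_splits(X, y, groups, folds, seed, grouping):
    y = np.asarray(y)
    if grouping == "run" and groups is not None and len(set(groups)) >= folds:
        return list(GroupKFold(n_splits=folds).split(X, y, np.asarray(groups)))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(cv.split(X, y))


def _cv_accuracy(X: pd.DataFrame, y: np.ndarray, folds: int, seed: int,
                 groups=None, grouping: str = "none") -> tuple:
    accs = []
    for k, (tr, te) in enumerate(_cv_splits(X, y, groups, folds, seed, grouping)):
        if len(np.unique(y[tr])) < 2:      # degenerate fold: resplit stratified
            tr2 = _cv_splits(X, y, None, folds, seed + 1, "none")[k]
            tr, te = tr2
        clf = make_classifier(seed)
        clf.fit(X.iloc[tr], y[tr])
        accs.append(float((clf.predict(X.iloc[te]) == y[te]).mean()))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1) / np.sqrt(len(accs)))


def sequential_feature_classification(table: pd.DataFrame, folds: int = 10,
                                      seed: int = 0,
                                      feature_order: Sequence[str] = FEATURE_ORDER,
                                      grouping: str = "run",
                                      n_shuffles: int = 1) -> pd.DataFrame:
    """Accuracy as EP features are added one at a time, with a shuffled-label
    control curve under the identical protocol.

    Returns a tidy frame with columns ``n_features, features, accuracy, sem,
    shuffled_accuracy, shuffled_sem``.
    """
    y = table["stim_group"].to_numpy()
    groups = table["run_id"].to_numpy() if "run_id" in table else None
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, len(feature_order) + 1):
        cols = list(feature_order[:k])
        X = table[cols].copy()
        acc, sem = _cv_accuracy(X, y, folds, seed, groups, grouping)
        sh_accs = []
        for s in range(n_shuffles):
            y_sh = rng.permutation(y)
            a, _ = _cv_accuracy(X, y_sh, folds, seed + 17 + s, groups, grouping)
            sh_accs.append(a)
        rows.append(dict(n_features=k, features="+".join(cols), accuracy=acc,
                         sem=sem, shuffled_accuracy=float(np.mean(sh_accs)),
                         shuffled_sem=float(np.std(sh_accs)) if n_shuffles > 1
                         else np.nan))
    return pd.DataFrame(rows)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray     # (rows, d)
    n_neighbors: int
    min_dist: float
    seed: int


def embed_waveforms(waveforms: np.ndarray, d: int = 2, n_neighbors: int = 15,
                    min_dist: float = 0.1, seed: int = 1234) -> EmbeddingResult:
    """UMAP embedding of EP waveforms (rows = contacts, columns = time).

    The time axis is treated as the feature dimension and reduced to ``d``
    layout coordinates with n_neighbors 15, min_dist 0.1, Euclidean metric
    and a fixed, recorded seed.
    """
    import umap

    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2:
        raise ValueError("waveforms must be 2-D (rows x time)")
    if W.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} waveforms, got {W.shape[0]}")
    if not (2 <= d <= 100):
        raise ValueError("embedding dimension must be in [2, 100]")
    reducer = umap.UMAP(n_components=d, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric="euclidean",
                        random_state=seed)
    coords = reducer.fit_transform(W)
    return EmbeddingResult(coordinates=np.asarray(coords), n_neighbors=n_neighbors,
                           min_dist=min_dist, seed=seed)


def embedding_classification(emb: EmbeddingResult, labels: Sequence[str],
                             roi: Optional[Sequence[str]] = None,
                             folds: int = 10, seed: int = 0,
                             groups=None, grouping: str = "none",
                             n_shuffles: int = 1) -> dict:
    """Cross-validated stimulation-site decoding from embedding coordinates,
    optionally adding ROI identity as a categorical feature."""
    X = pd.DataFrame(emb.coordinates,
                     columns=[f"u{i + 1}" for i in range(emb.coordinates.shape[1])])
    if roi is not None:
        X["roi"] = pd.Categorical(list(roi))
    y = np.asarray(list(labels))
    acc, sem = _cv_accuracy(X, y, folds, seed, groups, grouping)
    rng = np.random.default_rng(seed)
    sh = [_cv_accuracy(X, rng.permutation(y), folds, seed + 17 + s, groups,
                       grouping)[0] for s in range(n_shuffles)]
    return dict(accuracy=acc, sem=sem, shuffled_accuracy=float(np.mean(sh)),
                d=emb.coordinates.shape[1], with_roi=roi is not None)


def latency_group_map(emb: EmbeddingResult, labels: Sequence[str],
                      grid_n: int = 400, margin: float = 0.05,
                      seed: int = 0) -> dict:
    """Decision map of latency groupings in the 2-D embedding plane.

    Fits the classifier on the embedded points, evaluates predictions on a
    ``grid_n x grid_n`` grid spanning the bounding box (with a 5% margin),
    and reports per-group accuracy as the fraction of each group's points
    correctly classified.
    """
    P = emb.coordinates
    if P.shape[1] != 2:
        raise ValueError("latency map requires a 2-D embedding")
    y = np.asarray(list(labels))
    uniq = np.unique(y)
    if len(uniq) < 3:
        raise ValueError("need three non-empty latency groups")
    X = pd.DataFrame(P, columns=["u1", "u2"])
    clf = make_classifier(seed)
    clf.fit(X, y)
    lo, hi = P.min(axis=0), P.max(axis=0)
    pad = margin * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_n)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_n)
    GX, GY = np.meshgrid(gx, gy)
    grid = pd.DataFrame(np.column_stack([GX.ravel(), GY.ravel()]),
                        columns=["u1", "u2"])
    pred_grid = clf.predict(grid).reshape(grid_n, grid_n)
    pred_pts = clf.predict(X)
    per_group = {g: float((pred_pts[y == g] == g).mean()) for g in uniq}
    return dict(grid=pred_grid, x=gx, y=gy, per_group_accuracy=per_group)
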