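"""Untargeted per-spot feature tables and downstream phenotype statistics.

Builds a spots x features table by tolerance-clustering peak m/z values
across pixels and integrating each feature over every spot, prioritizes the
most abundant features for screening (top 500 by default), and implements
the two comparisons used for strain phenotyping: PCA of per-spot profiles
and volcano differential analysis (Welch's t-test on log2 intensities with
joint p <= 0.05, |fold change| >= 2 significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scistats
from sklearn.decomposition import PCA

from .errors import StatsError
from .io import LineScanRun, SpotLayout
from .quant import FeatureTable

log = logging.getLogger(__name__)


def detect_features(
    run: LineScanRun,
    layout: SpotLayout,
    top_n: int = 500,
    cluster_ppm: float = 10.0,
    min_total_intensity: float = 0.0,
) -> FeatureTable:
    """Cluster peak m/z values into features and integrate them per spot.

    Peaks from all pixels are pooled, sorted by m/z and clustered by
    single-linkage: a new feature starts wherever the gap to the previous
    peak exceeds ``cluster_ppm``. Each feature's per-spot value is the sum of
    its peak intensities over the pixels inside that spot. The ``top_n``
    features by total integrated intensity across sample-role spots are
    retained; when fewer are detected, all are kept with a logged note.
    """
    if top_n < 1:
        raise StatsError("top_n must be >= 1")
    distances = run.distances
    if layout.scan_length < distances[-1]:
        raise StatsError("layout extent shorter than the run")

    # pixel -> spot row index (-1 for gaps)
    spot_of_pixel = np.full(run.n_pixels, -1, dtype=np.int64)
    for row, spot in enumerate(layout.spots):
        spot_of_pixel[spot.contains(distances)] = row

    mz_all, int_all, pix_all = [], [], []
    for i, (_, spectrum) in enumerate(run.pixels):
        keep = spectrum.intensity > 0
        if keep.any():
            mz_all.append(spectrum.mz[keep])
            int_all.append(spectrum.intensity[keep])
            pix_all.append(np.full(keep.sum(), i, dtype=np.int64))
    if not mz_all:
        raise StatsError("run contains no nonzero peaks")
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    pix = np.concatenate(pix_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, pix = mz[order], inten[order], pix[order]

    gaps = np.diff(mz) > mz[:-1] * cluster_ppm * 1e-6
    cluster = np.concatenate([[0], np.cumsum(gaps)])
    n_clusters = int(cluster[-1]) + 1

    # intensity-weighted mean m/z per cluster
    w_sum = np.bincount(cluster, weights=inten, minlength=n_clusters)
    wm_sum = np.bincount(cluster, weights=inten * mz, minlength=n_clusters)
    feature_mz = np.where(w_sum > 0, wm_sum / np.maximum(w_sum, 1e-300), 0.0)

    n_spots = len(layout.spots)
    values = np.zeros((n_spots, n_clusters))
    spot_rows = spot_of_pixel[pix]
    in_spot = spot_rows >= 0
    flat = spot_rows[in_spot] * n_clusters + cluster[in_spot]
    values = np.bincount(
        flat, weights=inten[in_spot], minlength=n_spots * n_clusters
    ).reshape(n_spots, n_clusters)

    sample_rows = [i for i, s in enumerate(layout.spots) if s.role == "sample"]
    totals = values[sample_rows].sum(axis=0)
    keep = totals > min_total_intensity
    feature_mz, values, totals = feature_mz[keep], values[:, keep], totals[keep]

    if feature_mz.size > top_n:
        top = np.argsort(totals, kind="stable")[::-1][:top_n]
        top = np.sort(top)  # preserve m/z order
        feature_mz, values = feature_mz[top], values[:, top]
    else:
        log.info(
            "only %d features detected (top_n = %d); retaining all",
            feature_mz.size,
            top_n,
        )
    blanks = [s.label for s in layout.spots if s.role != "sample"]
    return FeatureTable(
        spot_labels=[s.label for s in layout.spots],
        feature_mzs=[float(f) for f in feature_mz],
        values=values,
        stage="raw",
        blank_labels=blanks,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # spots x components
    loadings: pd.DataFrame  # features x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_phenotypes(
    table: FeatureTable, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """Mean-centered PCA of per-spot profiles.

    With ``scale`` each feature is also divided by its standard deviation.
    Loadings expose per-feature contributions to each component, supporting
    the which-analyte-drives-PC1 reading of strain separations.
    """
    if table.n_spots < 2 or table.n_features < 2:
        raise StatsError("PCA needs at least 2 spots and 2 features")
    x = table.values.copy()
    if np.allclose(x, x[0]):
        raise StatsError("constant table; PCA undefined")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, table.n_spots - 1, table.n_features)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)  # sklearn mean-centers internally
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.spot_labels, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=table.feature_mzs, columns=comp_names
        ),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class VolcanoResult:
    feature_mz: float
    log2_fold_change: float
    p_value: float
    significant: bool
    direction: str  # up / down / none


def volcano(
    table: FeatureTable,
    group_a: list[str],
    group_b: list[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    epsilon: float | None = None,
    correction: str | None = None,
) -> list[VolcanoResult]:
    """Per-feature differential comparison of group_a against group_b.

    Fold change is mean(group_a) / mean(group_b) on the table's intensities
    (a pseudocount guards zero means); the p-value comes from Welch's
    two-sample t-test on log2(intensity + epsilon). A feature is significant
    when p <= ``p_threshold`` and |fold change| >= ``fc_threshold`` jointly;
    direction follows the fold-change sign. ``correction='bh'`` applies
    Benjamini-Hochberg adjustment to the p-values first (off by default —
    the thresholds are conventionally applied to raw p-values).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise StatsError("each group needs at least 2 replicates")
    a = np.stack([table.row(lb) for lb in group_a])
    b = np.stack([table.row(lb) for lb in group_b])
    if epsilon is None:
        top = float(max(table.values.max(), 1.0))
        epsilon = 1e-6 * top
    log_a = np.log2(a + epsilon)
    log_b = np.log2(b + epsilon)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # zero-variance columns trip scipy's precision-loss warning; their
        # p-values come back NaN and are set to 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pvals = _scistats.ttest_ind(log_a, log_b, axis=0, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    if correction == "bh":
        pvals = _benjamini_hochberg(pvals)
    elif correction is not None:
        raise StatsError(f"unknown correction {correction!r}")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log2fc = np.log2((mean_a + epsilon) / (mean_b + epsilon))
    log2_thr = np.log2(fc_threshold)
    results = []
    for j, mz in enumerate(table.feature_mzs):
        sig = bool(pvals[j] <= p_threshold and abs(log2fc[j]) >= log2_thr)
        direction = "none"
        if sig:
            direction = "up" if log2fc[j] > 0 else "down"
        results.append(
            VolcanoResult(
                feature_mz=float(mz),
                log2_fold_change=float(log2fc[j]),
                p_value=float(pvals[j]),
                significant=sig,
                direction=direction,
            )
        )
    return results


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def volcano_frame(results: list[VolcanoResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_mz": [r.feature_mz for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    )


def significant_counts(results: list[VolcanoResult]) -> dict[str, int]:
    """Totals of significant / up / down features in a volcano result."""
    sig = [r for r in results if r.significant]
    return {
        "significant": len(sig),
        "up": sum(1 for r in sig if r.direction == "up"),
        "down": sum(1 for r in sig if r.direction == "down"),
    }
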