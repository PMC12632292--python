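"""Continuous growth profiles, Ward clustering, and bilateral symmetry.

Fitted regional growth models are sampled on a dense gestational-age grid
(22.0-32.0 wGA, step 0.1, 101 samples); instantaneous relative growth rates
are finite differences normalized by the baseline value (the fitted value
at 22.0 wGA), in percent per week, assigned to interval midpoints
(22.05 ... 31.95). Baseline normalization makes rate curves invariant to
the absolute scale of a measure, so regions of very different sizes can be
clustered by trajectory shape alone.

Hierarchical Ward clustering groups the rate curves; the cluster count is
chosen by mean silhouette over a candidate range (with an optional manual
override mirroring dendrogram inspection). Cluster-averaged curves are
summarized by peak rate, peak time, AUC (cumulative growth), and growth
density (SD of the smoothed rate curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "GA_GRID",
    "GA_MIDPOINTS",
    "GrowthProfile",
    "ClusterSolution",
    "growth_profile",
    "cluster_metrics",
    "ward_cluster",
    "bilateral_symmetry",
]

GA_GRID: np.ndarray = np.round(22.0 + 0.1 * np.arange(101), 10)  # 22.0 ... 32.0
GA_MIDPOINTS: np.ndarray = np.round(0.5 * (GA_GRID[:-1] + GA_GRID[1:]), 10)

GRID_STEP = 0.1


@dataclass
class GrowthProfile:
    """Dense fitted curve and baseline-normalized rate for one trajectory."""

    region: str
    hemisphere: str
    metric: str
    values: np.ndarray      # fitted curve on GA_GRID
    baseline: float         # fitted value at 22.0 wGA
    rate: np.ndarray        # %/week on GA_MIDPOINTS

    @property
    def auc(self) -> float:
        """Cumulative growth: Riemann sum of the rate curve (% of baseline)."""
        return float(np.sum(self.rate) * GRID_STEP)


def growth_profile(model, region: str = "", hemisphere: str = "",
                   metric: str = "") -> GrowthProfile:
    """Sample a fitted growth model on the dense GA grid.

    rate_i = 100 * (v_{i+1} - v_i) / (0.1 * baseline), assigned to the
    interval midpoint; baseline is the fitted value at 22.0 wGA and must be
    positive. By the telescoping of the finite differences, the AUC of the
    rate curve equals 100 * (v(32) - v(22)) / v(22) exactly.
    """
    values = np.asarray(model.predict(GA_GRID), dtype=float)
    baseline = float(values[0])
    if baseline <= 0:
        raise ValueError(f"nonpositive baseline {baseline:.4g} at 22.0 wGA")
    rate = 100.0 * np.diff(values) / (GRID_STEP * baseline)
    return GrowthProfile(region, hemisphere, metric, values, baseline, rate)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (shorter) windows at the edges."""
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def cluster_metrics(mean_rate_curve, smoothing_window_weeks: float = 0.5
                    ) -> dict[str, float]:
    """Summary metrics of one (cluster-averaged) rate curve.

    peak_rate: maximum of the raw rate curve (%/week); peak_time: midpoint
    GA at the maximum, earliest on ties; auc: Riemann sum (rate * 0.1), the
    cumulative growth in % of baseline; growth_density: SD of the rate curve
    smoothed with a centered moving average (default window 0.5 weeks = 5
    samples, truncated at the edges).
    """
    rate = np.asarray(mean_rate_curve, dtype=float)
    if rate.size == 0:
        raise ValueError("empty rate curve")
    if rate.size != GA_MIDPOINTS.size:
        raise ValueError("rate curve must live on the midpoint grid")
    i = int(np.argmax(rate))  # argmax returns the first (earliest) maximum
    window = max(1, int(round(smoothing_window_weeks / GRID_STEP)))
    smoothed = _moving_average(rate, window)
    return {
        "peak_rate": float(rate[i]),
        "peak_time": float(GA_MIDPOINTS[i]),
        "auc": float(np.sum(rate) * GRID_STEP),
        "growth_density": float(np.std(smoothed)),
    }


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray                   # cluster id in 1..k per profile
    silhouette_by_k: dict[int, float]
    linkage_matrix: np.ndarray
    cluster_metrics: pd.DataFrame        # per cluster summary metrics
    mean_curves: dict[int, np.ndarray]   # cluster-averaged rate curves
    degenerate: bool = False             # all profiles identical
    overridden: bool = False             # k fixed by hand, not by silhouette


def ward_cluster(rate_curves: np.ndarray, k_candidates=range(2, 9),
                 override_k: int | None = None,
                 smoothing_window_weeks: float = 0.5) -> ClusterSolution:
    """Ward hierarchical clustering of rate curves with silhouette selection.

    ``rate_curves`` is (n_profiles, n_midpoints); distances are Euclidean
    between rate curves. For each candidate k the mean silhouette is
    computed; the chosen k maximizes it unless ``override_k`` is given
    (the analysis analogue of dendrogram inspection). Identical profiles are
    a flagged degenerate case with k forced to 1.
    """
    X = np.asarray(rate_curves, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 profiles to cluster")

    if np.allclose(X, X[0]):
        lab = np.ones(n, dtype=int)
        metrics = pd.DataFrame(
            [dict(cluster=1, n=n, **cluster_metrics(X.mean(axis=0),
                                                    smoothing_window_weeks))]
        ).set_index("cluster")
        return ClusterSolution(1, lab, {}, np.empty((0, 4)), metrics,
                               {1: X.mean(axis=0)}, degenerate=True)

    k_candidates = [int(k) for k in k_candidates]
    if any(k < 2 or k > n - 1 for k in k_candidates):
        raise ValueError(f"k candidates must lie in [2, {n - 1}]")

    Z = linkage(X, method="ward")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, lab, metric="euclidean"))

    if override_k is not None:
        k = int(override_k)
        if k not in labels_by_k:
            labels_by_k[k] = fcluster(Z, t=k, criterion="maxclust")
        overridden = True
    else:
        k = max(sil, key=lambda kk: (sil[kk], -kk))
        overridden = False
    labels = labels_by_k[k]

    rows = []
    curves = {}
    for c in range(1, k + 1):
        members = X[labels == c]
        mean_curve = members.mean(axis=0)
        curves[c] = mean_curve
        rows.append(dict(cluster=c, n=int(members.shape[0]),
                         **cluster_metrics(mean_curve, smoothing_window_weeks)))
    metrics = pd.DataFrame(rows).set_index("cluster")
    return ClusterSolution(k, labels, sil, Z, metrics, curves,
                           overridden=overridden)


def bilateral_symmetry(labels: pd.DataFrame) -> pd.DataFrame:
    """Homotopic cluster-assignment symmetry matrix.

    ``labels`` has columns region, hemisphere, cluster with both hemispheres
    present for every region. Cell (i, j) = number of regions whose left
    hemisphere is in cluster i and right in cluster j, divided by the number
    of unique regions with either hemisphere in cluster i or j. The diagonal
    is the homotopic consistency of each cluster (1 iff all contributing
    regions co-cluster bilaterally).
    """
    piv = labels.pivot(index="region", columns="hemisphere", values="cluster")
    if piv.isna().any().any() or not {"L", "R"}.issubset(piv.columns):
        raise ValueError("every region needs both hemispheres labeled")
    clusters = sorted(set(labels["cluster"]))
    mat = pd.DataFrame(0.0, index=clusters, columns=clusters)
    for i in clusters:
        for j in clusters:
            pairs = int(((piv["L"] == i) & (piv["R"] == j)).sum())
            contrib = int(((piv["L"] == i) | (piv["R"] == i) |
                           (piv["L"] == j) | (piv["R"] == j)).sum())
            mat.loc[i, j] = pairs / contrib if contrib else 0.0
    return mat
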