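"""K-means clustering of samples in scaled WE-score space.

Samples are points in pathway-dimensional space (their scaled WE score
profiles).  The number of clusters is chosen from the total within-cluster
sum of squares (WSS) curve over k = 1..k_max by a normalized
maximum-chord-distance elbow rule; the chosen partition is relabeled so
that cluster ordinals follow ascending grand-mean scaled WE — for k = 3
these are the DDR Low / Intermediate / High phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .scoring import WEScoreMatrix

__all__ = [
    "WSSCurve",
    "ClusterSolution",
    "wss_curve",
    "select_k",
    "cluster",
    "cluster_summary",
    "K3_LABELS",
]

K3_LABELS = ("DDR Low", "DDR Intermediate", "DDR High")


@dataclass
class WSSCurve:
    """Total within-cluster sum of squares for k = 1..k_max."""

    k_values: np.ndarray
    wss: np.ndarray
    restarts: int
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.wss).all() or (self.wss < 0).any():
            raise ValueError("WSS values must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "wss": self.wss})


@dataclass
class ClusterSolution:
    """A k-means partition with ordinal phenotype labels.

    ``assignments`` maps sample id -> cluster index in 0..k-1, where indices
    are already ordered by ascending grand-mean scaled WE of cluster
    members; ``labels`` maps each index to its display name.
    """

    k: int
    assignments: pd.Series
    centroids: np.ndarray
    labels: dict[int, str]
    wss_curve: WSSCurve | None
    seed: int

    @property
    def label_series(self) -> pd.Series:
        return self.assignments.map(self.labels).rename("label")


def _points(scaled: WEScoreMatrix) -> tuple[np.ndarray, pd.Index]:
    if scaled.scaled is None:
        raise ValueError("WEScoreMatrix has no scaled scores; run scale_we_scores first")
    return scaled.scaled.to_numpy(dtype=float).T, scaled.scaled.columns


def _best_kmeans(
    x: np.ndarray, k: int, restarts: int, rng: np.random.Generator,
    warm_centroids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd's k-means (k-means++ init).

    When ``warm_centroids`` (the best solution for k-1) is given, one extra
    candidate run is seeded from those centroids plus the sample farthest
    from its assigned centroid.  Splitting off that point cannot increase
    WSS, so the k-curve is non-increasing by construction.
    """
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(x)
    labels, centroids, wss = km.labels_, km.cluster_centers_, km.inertia_
    if warm_centroids is not None and warm_centroids.shape[0] == k - 1:
        d2 = ((x[:, None, :] - warm_centroids[None, :, :]) ** 2).sum(axis=2)
        worst = int(np.argmax(d2.min(axis=1)))
        init = np.vstack([warm_centroids, x[worst]])
        km2 = KMeans(n_clusters=k, init=init, n_init=1).fit(x)
        if km2.inertia_ < wss:
            labels, centroids, wss = km2.labels_, km2.cluster_centers_, km2.inertia_
    return labels, centroids, float(wss)


def wss_curve(
    scaled: WEScoreMatrix, k_max: int = 10, restarts: int = 25, seed: int = 0
) -> WSSCurve:
    """WSS for k = 1..k_max, deterministic for a fixed seed.

    wss[k=1] is the total sum of squared deviations from the grand
    centroid; for k >= 2 each value is the best of ``restarts`` k-means
    runs, with the (k-1)-solution's split refinement as an extra candidate
    so the curve is non-increasing.
    """
    x, _ = _points(scaled)
    n = x.shape[0]
    if n <= k_max:
        raise ValueError(
            f"need more samples ({n}) than k_max ({k_max}); reduce k_max"
        )
    rng = np.random.default_rng(seed)
    wss = np.empty(k_max, dtype=float)
    wss[0] = float(((x - x.mean(axis=0)) ** 2).sum())
    prev_centroids: np.ndarray | None = x.mean(axis=0, keepdims=True)
    for k in range(2, k_max + 1):
        _, centroids, w = _best_kmeans(x, k, restarts, rng, warm_centroids=prev_centroids)
        wss[k - 1] = w
        prev_centroids = centroids
    return WSSCurve(
        k_values=np.arange(1, k_max + 1), wss=wss, restarts=restarts, seed=seed
    )


def select_k(curve: WSSCurve) -> int:
    """Elbow pick: maximum vertical chord distance on the normalized curve.

    Both axes are min-max normalized; the chord joins (1, wss[1]) to
    (k_max, wss[k_max]); candidates are k in 2..k_max-1 (a 1-cluster
    "solution" is not a clustering, and the endpoint has zero distance by
    construction).  Ties break toward smaller k; a flat curve returns 2
    with a warning.
    """
    k = curve.k_values.astype(float)
    w = curve.wss.astype(float)
    if len(k) < 3:
        raise ValueError("elbow selection needs k_max >= 3")
    span = w[0] - w[-1]
    if span <= 0:
        warnings.warn("flat WSS curve; returning k=2", stacklevel=2)
        return 2
    kn = (k - k[0]) / (k[-1] - k[0])
    wn = (w - w[-1]) / span
    chord = 1.0 - kn  # normalized chord from (0, 1) to (1, 0)
    dist = chord - wn
    inner = slice(1, len(k) - 1)
    best = int(np.argmax(dist[inner])) + 1
    if dist[inner].max() <= 1e-12:
        warnings.warn("WSS curve has no elbow (linear); returning k=2", stacklevel=2)
        return 2
    return int(k[best])


def _order_by_grand_mean(
    labels: np.ndarray, x: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 0..k-1 by ascending grand-mean coordinate of members."""
    grand = np.array([x[labels == c].mean() for c in range(k)])
    order = np.argsort(grand, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels], order


def cluster(
    scaled: WEScoreMatrix,
    k: int,
    restarts: int = 25,
    seed: int = 0,
    wss: WSSCurve | None = None,
) -> ClusterSolution:
    """Best-of-restarts k-means with ordinal DDR phenotype labels.

    Clusters are relabeled by ascending grand-mean scaled WE of their
    members; for k = 3 the labels are DDR Low / DDR Intermediate / DDR
    High, otherwise DDR-1..DDR-k ascending.  An empty cluster triggers a
    re-run with a new seed (up to 10 attempts).
    """
    x, sample_ids = _points(scaled)
    n = x.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        labels, centroids, _ = _best_kmeans(x, k, restarts, rng)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError(f"k-means produced an empty cluster in 10 attempts (k={k})")
    ordered, order = _order_by_grand_mean(labels, x, k)
    centroids = centroids[order]
    if k == 3:
        names = dict(enumerate(K3_LABELS))
    else:
        names = {i: f"DDR-{i + 1}" for i in range(k)}
    return ClusterSolution(
        k=k,
        assignments=pd.Series(ordered, index=sample_ids, name="cluster"),
        centroids=centroids,
        labels=names,
        wss_curve=wss,
        seed=seed,
    )


def cluster_summary(sol: ClusterSolution, scaled: WEScoreMatrix) -> pd.DataFrame:
    """Per-cluster size, prevalence, grand-mean and per-pathway mean scaled WE."""
    if scaled.scaled is None:
        raise ValueError("scaled scores required")
    rows = []
    n_total = len(sol.assignments)
    for idx in range(sol.k):
        members = sol.assignments.index[sol.assignments == idx]
        sub = scaled.scaled[members]
        row = {
            "label": sol.labels[idx],
            "n_samples": len(members),
            "prevalence": len(members) / n_total,
            "grand_mean_we": float(sub.to_numpy().mean()),
        }
        for pathway in scaled.scaled.index:
            row[f"mean_we[{pathway}]"] = float(sub.loc[pathway].mean())
        rows.append(row)
    return pd.DataFrame(rows)
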