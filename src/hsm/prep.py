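"""Occurrence preparation: spatial thinning, spatial folds, background points.

Thinning enforces a minimum nearest-neighbor distance between retained
records (one roost record per 50 m cell in the default configuration)
using randomized greedy elimination with repeated trials, keeping the
largest surviving set. Spatial cross-validation folds are built by
k-means clustering of the point coordinates, replacing a manual
delineation of geographic clusters. Background points are sampled
uniformly over the valid study-area cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .raster import RasterStack
from .swd import OccurrenceSet

__all__ = ["FoldScheme", "thin", "make_folds", "sample_background", "assign_background_folds"]


@dataclass
class FoldScheme:
    """Spatial fold assignment for a set of occurrences."""

    k: int
    labels: np.ndarray  # fold id 1..k per occurrence
    method: str = "kmeans-xy"
    seed: int | None = None
    centroids: np.ndarray | None = None  # (k, 2), ordered west to east

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k} with no empty fold")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def thin(points: OccurrenceSet, min_dist: float, seed=0, *, n_trials: int = 10) -> OccurrenceSet:
    """Thin occurrences to a minimum pairwise distance.

    Iteratively removes the point with the most neighbors closer than
    ``min_dist`` (ties broken uniformly at random), repeated over
    ``n_trials`` randomized trials; the largest surviving set wins (spThin
    behavior). Points are canonicalized by (x, y) order first, so the
    result does not depend on input ordering. Deterministic per seed.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    n = len(points)
    if n == 0:
        return points
    order = np.lexsort((points.points[:, 1], points.points[:, 0]))
    xy = points.points[order]
    d = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    close = (d < min_dist) & ~np.eye(n, dtype=bool)
    if not close.any() or min_dist == 0:
        return points

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(n_trials):
        alive = np.ones(n, dtype=bool)
        counts = close.sum(axis=1).astype(float)
        while True:
            mx = counts[alive].max() if alive.any() else 0
            if mx <= 0:
                break
            cand = np.nonzero(alive & (counts == mx))[0]
            drop = cand[rng.integers(len(cand))]
            alive[drop] = False
            counts[close[drop]] -= 1
            counts[drop] = 0
        if best is None or alive.sum() > best.sum():
            best = alive.copy()
    kept_sorted = np.nonzero(best)[0]
    kept_original = np.sort(order[kept_sorted])
    return points.take(kept_original)


def make_folds(
    points: OccurrenceSet, k: int, seed=0, *, n_init: int = 10, allow_single: bool = False
) -> FoldScheme:
    """Build k spatial folds by k-means on projected coordinates.

    Cluster labels are renumbered 1..k west to east by cluster centroid so
    fold identity is reproducible across runs. ``k = 1`` is refused unless
    ``allow_single`` (single-fold schemes are only useful for diagnostics).
    """
    n = len(points)
    if k > n:
        raise ValueError("k cannot exceed the number of points")
    if k < 2 and not allow_single:
        raise ValueError("modeling requires k >= 2 spatial folds")
    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1)) if not isinstance(seed, int) else seed
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed_int)
    raw = km.fit_predict(points.points)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")  # west -> east
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    return FoldScheme(
        k=k,
        labels=labels,
        seed=seed_int,
        centroids=km.cluster_centers_[order],
    )


def sample_background(stack: RasterStack, n: int, seed=0, *, species: str = "background") -> OccurrenceSet:
    """Sample n background points uniformly over the valid study area.

    Cells are drawn uniformly with replacement from valid mask cells (so
    points may share cells) and positions jittered uniformly within the
    cell. Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(stack.mask)
    idx = rng.integers(len(rows), size=n)
    x0, y0 = stack.origin
    cs = stack.cell_size
    x = x0 + (cols[idx] + rng.uniform(0, 1, n)) * cs
    y = y0 - (rows[idx] + rng.uniform(0, 1, n)) * cs
    return OccurrenceSet(species=species, points=np.column_stack([x, y]), crs=stack.crs)


def assign_background_folds(background: OccurrenceSet, scheme: FoldScheme) -> OccurrenceSet:
    """Label background points with the fold of the nearest cluster centroid.

    Fold-aware scoring needs held-out background; with study-wide random
    background the natural assignment is by proximity to the occurrence
    clusters that define the folds.
    """
    if scheme.centroids is None:
        raise ValueError("fold scheme carries no centroids")
    d2 = ((background.points[:, None, :] - scheme.centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1) + 1
    return background.with_fold(labels)
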