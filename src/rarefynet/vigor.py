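"""Three-class vigor zoning of NDVI maps by multi-restart K-means.

Each NDVI map is clustered independently (class boundaries are per-map, not
shared).  Every fit runs 15 consecutive k-means++/Elkan restarts with at most
500 iterations and tolerance 1e-4, and the restart with the lowest
within-cluster sum of squares (WCSS) wins.  Classes are relabelled so that
L < M < H in centroid NDVI.  Individual restarts delegate to
scikit-learn's ``KMeans`` (the same k-means++/Elkan solver); the restart
loop is explicit so the per-restart WCSS log and the winning run index are
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .raster_io import GridTransform, NDVIMap

NODATA_CLASS = 255
CLASS_NAMES = ("L", "M", "H")


@dataclass
class KMeansResult:
    """Winning restart of a K-means fit on 1-D NDVI values.

    Centroids are sorted ascending and labels renumbered accordingly, so
    label 0/1/2 always means low/medium/high NDVI.
    """

    centroids: np.ndarray
    labels: np.ndarray
    wcss: float
    n_iter: int
    run_index: int
    wcss_per_restart: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class VigorMap:
    """Categorical L/M/H raster (0/1/2, 255 = nodata) with provenance."""

    classes: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    centroids: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def valid_labels(self) -> np.ndarray:
        return self.classes[self.mask]


def kmeans_fit(values, k: int = 3, n_init: int = 15, max_iter: int = 500,
               tol: float = 1e-4, seed: int | None = 0) -> KMeansResult:
    """Multi-restart K-means on 1-D NDVI values, lowest-WCSS restart selected.

    Deterministic for a fixed ``seed`` (restart seeds are spawned from it).

    Raises
    ------
    ValueError
        If fewer than ``k`` distinct values are available (degenerate input).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values to fit {k} clusters")
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2 ** 31)
    best = None
    wcss_log = np.empty(n_init)
    for run, run_seed in enumerate(restart_seeds):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                    tol=tol, algorithm="elkan", random_state=int(run_seed))
        km.fit(v[:, None])
        wcss_log[run] = km.inertia_
        if best is None or km.inertia_ < best[0]:
            best = (km.inertia_, km, run)
    wcss, km, run_index = best
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return KMeansResult(
        centroids=km.cluster_centers_.ravel()[order],
        labels=relabel[km.labels_],
        wcss=float(wcss),
        n_iter=int(km.n_iter_),
        run_index=int(run_index),
        wcss_per_restart=wcss_log,
    )


def assign_to_centroids(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; ties go to the lowest class index."""
    values = np.asarray(values, dtype=np.float64)
    d = np.abs(values[..., None] - np.asarray(centroids)[None, :])
    return np.argmin(d, axis=-1)


def classify_vigor(ndvi_map: NDVIMap, result: KMeansResult | None = None,
                   seed: int | None = 0) -> VigorMap:
    """Label every valid pixel of an NDVI map with its vigor class.

    When ``result`` is omitted, a fresh K-means fit is run on the map's valid
    pixels (per-map fitting: class boundaries are never shared across maps).
    Nodata cells are preserved as class 255.
    """
    valid = ndvi_map.valid_values
    if valid.size == 0:
        raise ValueError("cannot classify an all-nodata map")
    if result is None:
        result = kmeans_fit(valid, seed=seed)
    classes = np.full(ndvi_map.shape, NODATA_CLASS, dtype=np.uint8)
    classes[ndvi_map.mask] = assign_to_centroids(valid, result.centroids)
    return VigorMap(
        classes=classes,
        mask=ndvi_map.mask.copy(),
        transform=ndvi_map.transform,
        centroids=result.centroids.copy(),
        provenance={"wcss": result.wcss, "run_index": result.run_index,
                    "n_iter": result.n_iter},
    )
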