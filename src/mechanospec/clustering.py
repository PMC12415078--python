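"""K-means clustering of preprocessed Raman spectra into biochemical groups.

Cluster count selection evaluates three internal criteria (Silhouette,
Davies-Bouldin, Calinski-Harabasz) over a k range and takes a majority vote,
breaking ties toward the smaller k; the full criterion table is always
returned so the choice can be reviewed against the centroid biochemistry.
Off-target clusters (pure medium, or band-free "bad" spectra) can be
flagged and discarded before the mechanochemical statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_samples, silhouette_score)

__all__ = ["ClusterModel", "kmeans_cluster", "select_cluster_count",
           "silhouette_profile", "centroid_difference",
           "discard_offtarget_cluster", "spectra_matrix"]


@dataclass
class ClusterModel:
    """A fitted k-means model over a spectra matrix.

    Clusters are renumbered by descending size so that "cluster 0" is always
    the dominant component; ``centroids`` are mean spectra on the input
    scale (normalized like the inputs).
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wavenumber: np.ndarray
    wcss: float
    seed: int
    n_init: int
    degenerate: bool = False
    criterion_scores: pd.DataFrame | None = None
    silhouette_values: np.ndarray | None = None

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def spectra_matrix(spectra) -> tuple[np.ndarray, np.ndarray]:
    """Stack normalized RamanSpectrum objects into an (n, p) matrix."""
    axis = spectra[0].wavenumber
    for s in spectra[1:]:
        if s.wavenumber.size != axis.size or \
           not np.allclose(s.wavenumber, axis):
            raise ValueError("spectra share no common wavenumber axis")
    return np.vstack([s.intensity for s in spectra]), axis


def _relabel_by_size(labels: np.ndarray, k: int):
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    mapping = np.empty(k, dtype=int)
    mapping[order] = np.arange(k)
    return mapping[labels]


def kmeans_cluster(spectra, k: int, seed: int = 0,
                   n_init: int = 20) -> ClusterModel:
    """Lloyd's k-means (k-means++ init, best of ``n_init`` restarts).

    ``spectra`` is a list of normalized RamanSpectrum objects or an (n, p)
    array plus implicit axis.  Deterministic under a fixed seed.  If the
    data contain fewer distinct rows than k the model is flagged degenerate.
    """
    if isinstance(spectra, np.ndarray):
        mat, axis = spectra, np.arange(spectra.shape[1], dtype=float)
    else:
        mat, axis = spectra_matrix(spectra)
    n = mat.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n={n}]")
    n_distinct = np.unique(mat, axis=0).shape[0]
    degenerate = n_distinct < k
    if degenerate:
        warnings.warn(f"only {n_distinct} distinct spectra for k={k}; "
                      "clustering is degenerate", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn re-warns on duplicate points
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(mat)
    labels = _relabel_by_size(km.labels_, k)
    centroids = np.vstack([mat[labels == i].mean(axis=0) if np.any(labels == i)
                           else np.full(mat.shape[1], np.nan)
                           for i in range(k)])
    return ClusterModel(k=k, labels=labels, centroids=centroids,
                        wavenumber=axis, wcss=float(km.inertia_),
                        seed=seed, n_init=n_init, degenerate=degenerate)


def select_cluster_count(spectra, k_range, seed: int = 0,
                         n_init: int = 20) -> tuple[int, pd.DataFrame]:
    """Choose k by majority vote of Silhouette (max), Davies-Bouldin (min)
    and Calinski-Harabasz (max) over ``k_range``; ties toward smaller k.

    Returns (k_opt, table) where the table holds all per-k criterion values
    for review.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    if isinstance(spectra, np.ndarray):
        mat = spectra
    else:
        mat, _ = spectra_matrix(spectra)
    n = mat.shape[0]
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")

    rows = []
    for k in k_range:
        model = kmeans_cluster(mat, k, seed=seed, n_init=n_init)
        uniq = np.unique(model.labels)
        if uniq.size < 2:
            sil, db, ch = np.nan, np.nan, np.nan
        else:
            sil = silhouette_score(mat, model.labels)
            db = davies_bouldin_score(mat, model.labels)
            ch = calinski_harabasz_score(mat, model.labels)
        rows.append({"k": k, "silhouette": sil, "davies_bouldin": db,
                     "calinski_harabasz": ch, "wcss": model.wcss,
                     "degenerate": model.degenerate})
    table = pd.DataFrame(rows).set_index("k")

    votes = [
        table["silhouette"].idxmax(),
        table["davies_bouldin"].idxmin(),
        table["calinski_harabasz"].idxmax(),
    ]
    counts = pd.Series(votes).value_counts()
    top = counts[counts == counts.max()].index
    k_opt = int(min(top))
    return k_opt, table


def silhouette_profile(model: ClusterModel, mat: np.ndarray):
    """Per-point silhouette values s(i) = (b - a)/max(a, b) and per-cluster
    means.  Points in singleton clusters take the value 0 by convention."""
    uniq = np.unique(model.labels)
    if uniq.size < 2 or uniq.size >= mat.shape[0]:
        # single cluster, or every cluster a singleton: all values 0
        values = np.zeros(mat.shape[0])
    else:
        values = silhouette_samples(mat, model.labels)
        sizes = np.bincount(model.labels, minlength=model.k)
        values[sizes[model.labels] == 1] = 0.0
    per_cluster = {int(c): float(values[model.labels == c].mean())
                   for c in uniq}
    model.silhouette_values = values
    return values, per_cluster


def centroid_difference(model: ClusterModel, cluster_a: int,
                        cluster_b: int) -> np.ndarray:
    """Elementwise centroid_a - centroid_b, used to isolate the component
    that distinguishes two biochemical groups (e.g. glycogen bands)."""
    for c in (cluster_a, cluster_b):
        if not 0 <= c < model.k:
            raise ValueError(f"cluster {c} not in model")
    return model.centroids[cluster_a] - model.centroids[cluster_b]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu_ = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu_ == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu_ * nv))


def _max_band_prominence(centroid: np.ndarray) -> float:
    peaks, props = find_peaks(centroid, prominence=0.0)
    if peaks.size == 0:
        return 0.0
    return float(props["prominences"].max())


def discard_offtarget_cluster(model: ClusterModel,
                              medium_reference=None,
                              cosine_threshold: float = 0.95,
                              prominence_floor: float | None = None):
    """Flag clusters that are medium or band-free and drop their points.

    A cluster is off-target when its centroid matches the medium reference
    spectrum (cosine similarity above ``cosine_threshold``) or shows no
    detectable bands (maximum peak prominence below ``prominence_floor``;
    default: 20 % of the largest centroid prominence in the model).
    Returns (filtered_labels, n_discarded, discarded_clusters) where
    filtered labels are re-indexed 0..k'-1 by descending size and discarded
    points carry the label -1.
    """
    proms = np.array([_max_band_prominence(c) for c in model.centroids])
    if prominence_floor is None:
        prominence_floor = 0.2 * proms.max()
    discarded = []
    for i in range(model.k):
        if proms[i] < prominence_floor:
            discarded.append(i)
            continue
        if medium_reference is not None:
            ref = (medium_reference.intensity
                   if hasattr(medium_reference, "intensity")
                   else np.asarray(medium_reference))
            if _cosine(model.centroids[i], ref) > cosine_threshold:
                discarded.append(i)
    if len(discarded) == model.k:
        raise ValueError("all clusters flagged off-target")
    kept = [i for i in range(model.k) if i not in discarded]
    remap = {old: new for new, old in enumerate(kept)}
    out = np.array([remap.get(l, -1) for l in model.labels])
    n_discarded = int(np.sum(out == -1))
    return out, n_discarded, discarded
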