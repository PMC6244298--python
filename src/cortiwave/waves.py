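"""Propagation-pattern classification from delay features.

The delay feature vectors (one per spike event, one entry per good channel)
live close to a low-dimensional subspace: a plane wave's delay field is an
affine function of electrode position, so all plane waves together span at
most two directions, and spirals add roughly one more.  The pipeline
therefore mirrors that geometry:

1. PCA on the feature matrix (the first 3 components capture nearly all
   variance when the events are directional waves and spirals);
2. projection onto the leading components;
3. k-means clustering in the projected space, best of ``n_init`` seeded
   restarts (k-means is seed-dependent; restarts plus explicit seeds make
   runs reproducible);
4. elbow inspection of the within-cluster sum of squares W_k to choose k;
5. semantic labelling of each cluster from its centroid delay map — a
   planar fit names the cardinal propagation direction, a rotational
   (angle-linear) fit names a spiral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import GridGeometry, GridMap

__all__ = [
    "PCAModel",
    "WaveClustering",
    "ElbowCurve",
    "pca_fit",
    "project",
    "kmeans_cluster",
    "elbow_wk",
    "assign_semantic_labels",
]


@dataclass
class PCAModel:
    """Mean-centred PCA with a fixed sign convention.

    ``components`` is (n_features, n_components) with orthonormal columns;
    each column's largest-magnitude coefficient is made positive so
    component maps are reproducible across runs.
    """

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_fit(features: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Fit mean-centred PCA to the (n_events, n_features) feature matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (events x features)")
    n_comp = n_components if n_components is not None else min(X.shape)
    if X.shape[0] < n_comp:
        raise ValueError(
            f"{X.shape[0]} events cannot support {n_comp} components")
    p = PCA(n_components=n_comp, svd_solver="full")
    p.fit(X)
    comps = p.components_.copy()  # (n_comp, n_features)
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(components=comps.T,
                    explained_variance_ratio=p.explained_variance_ratio_.copy(),
                    mean=p.mean_.copy())


def project(features: np.ndarray, model: PCAModel, n: int = 3) -> np.ndarray:
    """Centred features projected onto the first ``n`` components."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"features have {X.shape[1]} columns, model expects {model.mean.size}")
    if n > model.components.shape[1]:
        raise ValueError(
            f"requested {n} components, model has {model.components.shape[1]}")
    return (X - model.mean) @ model.components[:, :n]


@dataclass
class WaveClustering:
    """k-means result: per-event cluster ids plus reproducibility metadata."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    seed: int
    n_init: int
    inertia: float
    semantic_labels: dict[int, str] = field(default_factory=dict)


def kmeans_cluster(projected: np.ndarray, k: int, seed: int = 0,
                   n_init: int = 50) -> WaveClustering:
    """Best-of-``n_init`` k-means (k-means++ seeding), deterministic per seed."""
    X = np.asarray(projected, dtype=float)
    if k < 2:
        raise ValueError("clustering needs k >= 2 (k = 1 only inside elbow_wk)")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} events cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return WaveClustering(labels=labels, centroids=km.cluster_centers_.copy(),
                          k=k, seed=seed, n_init=n_init, inertia=float(km.inertia_))


@dataclass
class ElbowCurve:
    """Within-cluster sum of squares per k, with the curvature-based elbow."""

    k_values: np.ndarray
    W_k: np.ndarray
    suggested_k: int
    low_confidence: bool


def elbow_wk(projected: np.ndarray, k_range: range | list[int],
             seed: int = 0, n_init: int = 10) -> ElbowCurve:
    """W_k over ``k_range`` plus the maximum-flattening elbow suggestion.

    The elbow is where the decrease of W_k flattens most sharply: the
    interior k maximizing the ratio of the decrease into k to the decrease
    out of it, ``(W_{k-1} - W_k) / (W_k - W_{k+1})``.  (A raw second
    difference is dominated by whichever single drop is largest on the
    absolute scale and misses elbows that follow a much bigger earlier
    drop; the ratio is scale-free.)  When no k flattens markedly more than
    the rest (max ratio under twice the median ratio), the suggestion is
    flagged low-confidence — a smooth curve means no natural cluster count.
    """
    X = np.asarray(projected, dtype=float)
    ks = np.asarray(sorted(k_range), dtype=int)
    if ks.min() < 1 or ks.max() > X.shape[0]:
        raise ValueError("k_range must lie within [1, n_events]")
    W = np.empty(ks.size)
    for i, k in enumerate(ks):
        if k == 1:
            W[i] = float(((X - X.mean(axis=0)) ** 2).sum())
        elif k == X.shape[0]:
            W[i] = 0.0
        else:
            km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed).fit(X)
            W[i] = float(km.inertia_)
    if ks.size >= 3:
        drops = W[:-1] - W[1:]
        eps = 1e-12 * max(float(W[0]), 1.0)
        ratios = drops[:-1] / np.maximum(drops[1:], eps)
        best = int(np.argmax(ratios))
        suggested = int(ks[1 + best])
        med = float(np.median(ratios))
        low_conf = not (med > 0 and ratios[best] >= 2 * med)
    else:
        suggested = int(ks[-1])
        low_conf = True
    return ElbowCurve(k_values=ks, W_k=W, suggested_k=suggested,
                      low_confidence=low_conf)


# ---------------------------------------------------------------------------
# Semantic labelling of clusters from centroid delay maps


def _plane_fit(values: np.ndarray, geometry: GridGeometry
               ) -> tuple[float, np.ndarray]:
    """Least-squares plane through the good-channel delays.

    Returns (R^2, gradient (d delay / d x, d delay / d y) in ms per um).
    """
    good = geometry.good_channels()
    pos = geometry.positions()[good]
    y = values[good]
    A = np.column_stack((np.ones(good.size), pos))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-12:
        return 0.0, np.zeros(2)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return r2, coef[1:]


def _angular_fit(values: np.ndarray, geometry: GridGeometry
                 ) -> tuple[float, float]:
    """Best rotational fit: delay linear in polar angle about a centre.

    Searches a coarse grid of candidate centres and branch cuts; returns
    (R^2, slope ms/rad).  A good fit (|slope| > 0) means the delay field
    winds once around the centre — the spiral signature.
    """
    good = geometry.good_channels()
    pos = geometry.positions()[good]
    y = values[good]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-12:
        return 0.0, 0.0
    x_span = pos[:, 0].min(), pos[:, 0].max()
    y_span = pos[:, 1].min(), pos[:, 1].max()
    fracs = (0.3, 0.5, 0.7)
    best_r2, best_slope = -np.inf, 0.0
    for fx in fracs:
        for fy in fracs:
            cx = x_span[0] + fx * (x_span[1] - x_span[0])
            cy = y_span[0] + fy * (y_span[1] - y_span[0])
            rel = pos - (cx, cy)
            if np.any(np.hypot(rel[:, 0], rel[:, 1]) < 1e-9):
                continue
            theta = np.arctan2(rel[:, 1], rel[:, 0])
            for cut in np.linspace(-np.pi, np.pi, 16, endpoint=False):
                th = np.mod(theta - cut, 2 * np.pi)
                A = np.column_stack((np.ones(good.size), th))
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ coef
                r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
                if r2 > best_r2:
                    best_r2, best_slope = r2, float(coef[1])
    return best_r2, best_slope


def _label_one_map(values: np.ndarray, geometry: GridGeometry,
                   r2_threshold: float = 0.8) -> str:
    plane_r2, grad = _plane_fit(values, geometry)
    if plane_r2 >= r2_threshold and np.hypot(*grad) > 0:
        gx, gy = grad  # delay grows along the travel direction
        if abs(gx) >= abs(gy):
            return "left_to_right" if gx > 0 else "right_to_left"
        return "top_to_bottom" if gy > 0 else "bottom_to_top"
    ang_r2, slope = _angular_fit(values, geometry)
    if ang_r2 >= r2_threshold and abs(slope) > 0:
        return "spiral"
    return "other"


def assign_semantic_labels(clustering: WaveClustering,
                           delay_maps: list[GridMap],
                           geometry: GridGeometry,
                           r2_threshold: float = 0.8) -> WaveClustering:
    """Name each cluster by the shape of its centroid delay map.

    Per cluster, member delay maps are averaged; a planar fit with
    R^2 >= ``r2_threshold`` gives a cardinal direction label
    (``right_to_left`` / ``left_to_right`` / ``top_to_bottom`` /
    ``bottom_to_top``), otherwise a rotational (angle-linear) fit names a
    ``spiral``; anything else is ``other``.
    """
    if len(delay_maps) != clustering.labels.size:
        raise ValueError("need exactly one delay map per clustered event")
    from .core import grid_to_channels

    vectors = np.array([grid_to_channels(gm, geometry) for gm in delay_maps])
    semantic: dict[int, str] = {}
    for c in range(clustering.k):
        members = vectors[clustering.labels == c]
        centroid = np.nanmean(members, axis=0)
        centroid = np.where(np.isfinite(centroid), centroid, 0.0)
        semantic[c] = _label_one_map(centroid, geometry, r2_threshold)
    clustering.semantic_labels = semantic
    return clustering
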