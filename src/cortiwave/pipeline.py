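"""End-to-end conveniences chaining the analysis stages.

These are thin compositions of the per-module operations, provided because
the same chains recur in scripts and in the CLI: delay features -> PCA ->
k-means -> semantic labels on one side, and common-mode subtraction ->
high-gamma filtering -> connectivity -> similarity -> communities on the
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MultichannelRecording
from .delays import delay_features, delay_map, delay_matrix
from .events import SpikeEvent, slice_window
from .netstates import ConnectionMatrix, NetworkPartition, connection_matrix, \
    detect_communities, similarity_graph
from .preprocess import apply_filter, subtract_common_mode
from .waves import WaveClustering, assign_semantic_labels, kmeans_cluster, \
    pca_fit, project

__all__ = ["WaveClassification", "classify_waves", "network_states_for_events"]


@dataclass
class WaveClassification:
    """Everything the wave-classification chain produces."""

    features: np.ndarray
    projected: np.ndarray
    clustering: WaveClustering
    reference: int
    explained_variance_ratio: np.ndarray


def classify_waves(events: list[SpikeEvent], k: int = 3, seed: int = 0,
                   n_init: int = 50, n_components: int = 3,
                   reference: int | None = None,
                   max_lag_ms: float | None = None) -> WaveClassification:
    """Delay features -> PCA -> k-means -> semantic labels for spike events."""
    feats, good, ref = delay_features(events, reference=reference,
                                      max_lag_ms=max_lag_ms)
    model = pca_fit(feats)
    proj = project(feats, model, n=min(n_components, model.components.shape[1]))
    clustering = kmeans_cluster(proj, k=k, seed=seed, n_init=n_init)
    geometry = events[0].geometry
    maps = [delay_map(delay_matrix_from_feature(feats[e], good, geometry, ref,
                                                events[e].event_id), ref)
            for e in range(len(events))]
    clustering = assign_semantic_labels(clustering, maps, geometry)
    return WaveClassification(features=feats, projected=proj,
                              clustering=clustering, reference=ref,
                              explained_variance_ratio=model.explained_variance_ratio)


def delay_matrix_from_feature(feature: np.ndarray, good: np.ndarray, geometry,
                              reference: int, event_id: int = -1):
    """Reference row/column of a delay matrix rebuilt from one feature vector.

    The feature vector IS the reference column, so the reference row of the
    matrix (all the delay map needs) is recoverable without recomputing the
    other pairs.
    """
    from .delays import DelayMatrix

    n_ch = geometry.n_channels
    d = np.full((n_ch, n_ch), np.nan)
    np.fill_diagonal(d, 0.0)
    d[reference, good] = feature
    d[good, reference] = -feature
    d[reference, reference] = 0.0
    q = np.full((n_ch, n_ch), np.nan)
    return DelayMatrix(d=d, quality=q, max_lag=np.nan, geometry=geometry,
                       event_id=event_id)


def network_states_for_events(rec_raw: MultichannelRecording,
                              events: list[SpikeEvent],
                              max_lag_ms: float = 20.0,
                              resolution: float = 1.0, seed: int = 0,
                              n_init: int = 50, envelope: bool = True
                              ) -> tuple[list[ConnectionMatrix], np.ndarray,
                                         NetworkPartition]:
    """Common-mode subtraction -> high-gamma filter -> per-event
    connectivity -> similarity graph -> community detection.

    The events' windows are re-cut from the raw recording so the
    connectivity band is filtered from unsmoothed data.
    """
    hg = apply_filter(subtract_common_mode(rec_raw), "high_gamma")
    cms = [connection_matrix(slice_window(hg, *ev.window), hg.fs, hg.geometry,
                             max_lag_ms=max_lag_ms, envelope=envelope,
                             event_id=ev.event_id)
           for ev in events]
    sim = similarity_graph(cms)
    partition = detect_communities(sim, resolution=resolution, seed=seed,
                                   n_init=n_init)
    return cms, sim, partition
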