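"""Functional network states from per-event high-gamma connectivity.

Each electrode is a node sensing the population directly beneath it.  For
every spike event, connectivity between two channels is the maximum over
signed lags of the Pearson-normalized cross-correlation of their
high-gamma (80-120 Hz) amplitude envelopes — a power-based measure that is
robust to the propagation delays the waves themselves introduce, which is
exactly why it can be compared against propagation type without bias.
(The raw band-passed signals can be correlated instead via
``envelope=False`` for sensitivity analysis.)

Events are then compared to each other: the similarity of two events is
the Pearson correlation of their vectorized connection matrices (strict
upper triangles — the matrices are symmetric with unit diagonal, so the
full matrix would double-count).  The resulting event-by-event similarity
matrix is an undirected weighted graph whose communities, found by
Louvain-style modularity maximization, are the network states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal

from .core import GridGeometry
from .delays import normalized_xcorr

__all__ = [
    "ConnectionMatrix",
    "NetworkPartition",
    "connection_matrix",
    "similarity_graph",
    "modularity",
    "detect_communities",
]


@dataclass
class ConnectionMatrix:
    """Symmetric per-event connectivity in [-1, 1] with unit diagonal.

    Rows/columns of bad or zero-variance channels are NaN.
    """

    c: np.ndarray
    event_id: int = -1
    band: tuple[float, float] = (80.0, 120.0)
    max_lag: float = 20.0


def connection_matrix(segment: np.ndarray, fs: float, geometry: GridGeometry,
                      max_lag_ms: float = 20.0, envelope: bool = True,
                      event_id: int = -1,
                      band: tuple[float, float] = (80.0, 120.0)
                      ) -> ConnectionMatrix:
    """Max-over-lag normalized cross-correlation connectivity for one event.

    ``segment`` must already be band-limited (high-gamma) and common-mode
    subtracted.  With ``envelope=True`` the analytic-signal magnitudes are
    correlated (power coupling); symmetry is automatic because the lag scan
    covers both signs.  Zero-variance channels are excluded with a warning.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] != geometry.n_channels:
        raise ValueError("segment must be (n_channels, n_samples)")
    good = geometry.good_channels()
    if good.size < 2:
        raise ValueError("need at least 2 good channels")
    sig = np.abs(signal.hilbert(seg, axis=-1)) if envelope else seg

    sd = sig[good].std(axis=-1)
    dead = [int(ch) for ch, s in zip(good, sd) if s == 0]
    if dead:
        warnings.warn(f"zero-variance channel(s) {dead} excluded from "
                      "connectivity", UserWarning)
    use = np.array([ch for ch in good if ch not in dead], dtype=int)

    max_lag = int(round(max_lag_ms * fs / 1e3))
    n_ch = geometry.n_channels
    c = np.full((n_ch, n_ch), np.nan)
    c[use, use] = 1.0
    for ii, i in enumerate(use):
        for j in use[ii + 1:]:
            _, r = normalized_xcorr(sig[i], sig[j], max_lag)
            c[i, j] = c[j, i] = float(r.max())
    return ConnectionMatrix(c=c, event_id=event_id, band=band, max_lag=max_lag_ms)


def similarity_graph(cms: list[ConnectionMatrix]) -> np.ndarray:
    """Event-by-event Pearson similarity of connection patterns.

    Each connection matrix is vectorized over the strict upper triangle of
    its finite entries (consistent across events); entry (m, n) of the
    returned matrix is the correlation of vectors m and n.  Symmetric with
    unit diagonal.
    """
    if len(cms) < 2:
        raise ValueError("need at least 2 events")
    finite = np.isfinite(cms[0].c)
    for cm in cms[1:]:
        finite &= np.isfinite(cm.c)
    iu = np.triu_indices_from(cms[0].c, k=1)
    keep = finite[iu]
    vecs = np.array([cm.c[iu][keep] for cm in cms])
    sds = vecs.std(axis=1)
    for m, s in enumerate(sds):
        if s == 0:
            raise ValueError(
                f"connection matrix of event {cms[m].event_id} is constant; "
                "similarity undefined")
    s = np.corrcoef(vecs)
    np.fill_diagonal(s, 1.0)
    return s


def _clip_graph(s: np.ndarray) -> tuple[np.ndarray, int]:
    """Self-loops removed, negative weights clipped to 0 (count returned)."""
    w = np.array(s, dtype=float, copy=True)
    np.fill_diagonal(w, 0.0)
    neg = int(np.sum(w < 0) // 2)
    np.clip(w, 0.0, None, out=w)
    return w, neg


def modularity(s: np.ndarray, communities: np.ndarray,
               resolution: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity Q of a partition.

    ``Q = sum_c [ e_c / m - resolution * (d_c / 2m)^2 ]`` with ``e_c`` the
    within-community edge weight, ``d_c`` the community's total weighted
    degree and ``m`` the total edge weight.  Negative similarities are
    clipped to zero first (modularity is defined for non-negative weights)
    and self-loops are dropped.  The all-in-one partition scores exactly 0.
    """
    labels = np.asarray(communities)
    w, _ = _clip_graph(s)
    m = w.sum() / 2.0
    if m == 0:
        return 0.0
    deg = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_c = w[np.ix_(idx, idx)].sum() / 2.0
        d_c = deg[idx].sum()
        q += e_c / m - resolution * (d_c / (2.0 * m)) ** 2
    return float(q)


@dataclass
class NetworkPartition:
    """Community assignment of events plus its modularity score."""

    communities: np.ndarray
    Q: float
    resolution: float
    seed: int
    n_clipped_edges: int = 0

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.communities).size)


def _greedy_local_moves(w: np.ndarray, labels: np.ndarray, resolution: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Greedy single-node moves (to any community or a new singleton) until
    no move increases Q — the flat Louvain phase-1 sweep from an arbitrary
    starting partition."""
    labels = labels.copy()
    n = w.shape[0]
    m = w.sum() / 2.0
    deg = w.sum(axis=1)
    while True:
        improved = False
        for i in rng.permutation(n):
            cur = int(labels[i])
            cands = set(labels.tolist())
            cands.add(int(labels.max()) + 1)
            cands.discard(cur)
            in_cur = labels == cur
            ki_cur = w[i, in_cur].sum()
            sum_cur = deg[in_cur].sum() - deg[i]
            best_dq, best_c = 1e-13, cur
            for c in cands:
                in_c = labels == c
                ki_c = w[i, in_c].sum()
                sum_c = deg[in_c].sum()
                dq = (ki_c - ki_cur) / m \
                    - resolution * deg[i] * (sum_c - sum_cur) / (2.0 * m * m)
                if dq > best_dq:
                    best_dq, best_c = dq, c
            if best_c != cur:
                labels[i] = best_c
                improved = True
        if not improved:
            return labels


def detect_communities(s: np.ndarray, resolution: float = 1.0, seed: int = 0,
                       n_init: int = 50) -> NetworkPartition:
    """Greedy modularity maximization on the similarity graph.

    Runs ``n_init`` seeded restarts and keeps the highest-Q partition, so
    results are deterministic given ``seed``.  Each restart combines a
    Louvain pass (multi-level, node order shuffled by the restart seed)
    with greedy single-node-move local searches — one polishing the
    Louvain result and one started from a random partition.  The mixed
    restarts escape the occasional local optimum that traps pure Louvain.

    Negative edges are clipped to zero and self-loops dropped before
    optimization.  If every edge clips to zero the graph carries no
    community signal and a single community is returned with a warning.
    """
    w, n_neg = _clip_graph(s)
    n = w.shape[0]
    if w.sum() == 0:
        warnings.warn("all similarity edges are <= 0; returning a single "
                      "community", UserWarning)
        return NetworkPartition(communities=np.zeros(n, dtype=int), Q=0.0,
                                resolution=resolution, seed=seed,
                                n_clipped_edges=n_neg)
    g = nx.from_numpy_array(w)
    best_part, best_q = None, -np.inf

    def consider(labels: np.ndarray) -> None:
        nonlocal best_part, best_q
        q = modularity(w, labels, resolution=resolution)
        if q > best_q:
            best_q, best_part = q, labels

    for s_i in range(n_init):
        rng = np.random.default_rng(int(seed) + s_i)
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(seed) + s_i)
        labels = np.empty(n, dtype=int)
        for cid, nodes in enumerate(comms):
            labels[list(nodes)] = cid
        consider(_greedy_local_moves(w, labels, resolution, rng))
        k0 = int(rng.integers(1, n + 1))
        consider(_greedy_local_moves(w, rng.integers(0, k0, n), resolution, rng))

    # canonical relabeling by first occurrence
    _, canon = np.unique(best_part, return_inverse=True)
    first_seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(best_part):
        if c not in first_seen:
            first_seen[c] = len(first_seen)
        out[i] = first_seen[c]
    return NetworkPartition(communities=out, Q=float(best_q),
                            resolution=resolution, seed=seed,
                            n_clipped_edges=n_neg)
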