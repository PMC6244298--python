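"""High-gamma connectivity, similarity graphs, modularity, communities."""

import itertools

import numpy as np
import pytest
from scipy import signal
from sklearn.metrics import adjusted_rand_score

from cortiwave import (GridGeometry, connection_matrix, detect_communities,
                       modularity, similarity_graph)
from cortiwave.netstates import ConnectionMatrix


def hg_bandpass(x, fs=1000.0):
    sos = signal.butter(4, (80, 120), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


class TestConnectionMatrix:
    def test_delayed_copy_fully_connected(self, grid8, rng):
        x = hg_bandpass(rng.normal(size=1000))
        seg = np.zeros((64, 1000))
        seg[0] = x
        seg[1] = np.roll(x, 10)  # 10 ms delay, within max_lag
        seg[2:] = hg_bandpass(rng.normal(size=(62, 1000)))
        cm = connection_matrix(seg, 1000.0, grid8, max_lag_ms=20.0)
        assert cm.c[0, 1] >= 1.0 - 1e-6

    def test_independent_noise_weakly_connected(self, grid8, rng):
        # Monte-Carlo null: mean off-diagonal connectivity stays small
        vals = []
        for _ in range(10):
            seg = hg_bandpass(rng.normal(size=(64, 1000)))
            cm = connection_matrix(seg, 1000.0, grid8, max_lag_ms=20.0)
            iu = np.triu_indices(64, 1)
            vals.append(np.abs(cm.c[iu]).mean())
        assert np.mean(vals) <= 0.15

    def test_planted_blocks_within_exceeds_across(self, grid8, rng):
        carriers = hg_bandpass(rng.normal(size=(64, 2000)))
        mod = 1 + 0.9 * np.tanh(
            signal.sosfiltfilt(signal.butter(4, 8, fs=1000.0, output="sos"),
                               rng.standard_normal(2000)))
        seg = carriers.copy()
        seg[:32] *= mod
        cm = connection_matrix(seg, 1000.0, grid8, max_lag_ms=20.0)
        mask = np.zeros(64, bool)
        mask[:32] = True
        iu = np.triu_indices(64, 1)
        same = (mask[:, None] == mask[None, :])[iu]
        assert cm.c[iu][same].mean() > cm.c[iu][~same].mean()

    def test_symmetric_unit_diagonal(self, grid8, rng):
        seg = hg_bandpass(rng.normal(size=(64, 500)))
        cm = connection_matrix(seg, 1000.0, grid8, max_lag_ms=10.0)
        np.testing.assert_array_equal(cm.c, cm.c.T)
        np.testing.assert_array_equal(np.diag(cm.c), 1.0)

    def test_amplitude_scaling_invariance(self, grid8, rng):
        seg = hg_bandpass(rng.normal(size=(64, 500)))
        cm1 = connection_matrix(seg, 1000.0, grid8, max_lag_ms=10.0)
        scales = rng.uniform(0.1, 10.0, size=64)
        cm2 = connection_matrix(seg * scales[:, None], 1000.0, grid8,
                                max_lag_ms=10.0)
        np.testing.assert_allclose(cm1.c, cm2.c, atol=1e-9)

    def test_zero_variance_channel_excluded_with_warning(self, grid8, rng):
        seg = hg_bandpass(rng.normal(size=(64, 500)))
        seg[3] = 0.0
        with pytest.warns(UserWarning, match=r"\[3\]"):
            cm = connection_matrix(seg, 1000.0, grid8, max_lag_ms=10.0,
                                   envelope=False)
        assert np.isnan(cm.c[3, 10])


def fake_cm(c, event_id=0):
    return ConnectionMatrix(c=c, event_id=event_id)


class TestSimilarityGraph:
    def test_duplicates_similarity_one(self, rng):
        c = np.corrcoef(rng.normal(size=(6, 50)))
        s = similarity_graph([fake_cm(c, 0), fake_cm(c, 1)])
        assert s[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_offdiagonal_similarity_minus_one(self, rng):
        c = np.corrcoef(rng.normal(size=(6, 50)))
        c2 = -c.copy()
        np.fill_diagonal(c2, 1.0)
        s = similarity_graph([fake_cm(c, 0), fake_cm(c2, 1)])
        assert s[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_triangle_correlation(self, rng):
        cms = [fake_cm(np.corrcoef(rng.normal(size=(8, 60))), i)
               for i in range(5)]
        s = similarity_graph(cms)
        iu = np.triu_indices(8, 1)
        for m in range(5):
            for n in range(m + 1, 5):
                direct = np.corrcoef(cms[m].c[iu], cms[n].c[iu])[0, 1]
                assert s[m, n] == pytest.approx(direct, abs=1e-12)

    def test_constant_matrix_rejected_with_event_named(self, rng):
        c_ok = np.corrcoef(rng.normal(size=(6, 50)))
        c_const = np.ones((6, 6))
        with pytest.raises(ValueError, match="event 7"):
            similarity_graph([fake_cm(c_ok, 0), fake_cm(c_const, 7)])


def all_partitions(n):
    """Restricted-growth-string enumeration of every set partition."""
    def rgs(prefix, m):
        if len(prefix) == n:
            yield prefix
            return
        for v in range(m + 1):
            yield from rgs(prefix + [v], max(m, v + 1))
    yield from rgs([], 0)


class TestModularity:
    def test_all_in_one_partition_scores_zero(self, rng):
        w = np.abs(rng.normal(size=(10, 10)))
        w = (w + w.T) / 2
        assert modularity(w, np.zeros(10, int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_score_half(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        assert modularity(w, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_matches_double_sum_oracle(self, rng):
        # independent formula: Q = (1/2m) sum_ij (w_ij - d_i d_j / 2m) delta
        for _ in range(20):
            n = int(rng.integers(4, 10))
            w = np.abs(rng.normal(size=(n, n)))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            labels = rng.integers(0, 3, n)
            m2 = w.sum()
            deg = w.sum(axis=1)
            q_oracle = sum(
                (w[i, j] - deg[i] * deg[j] / m2) / m2
                for i in range(n) for j in range(n) if labels[i] == labels[j])
            assert modularity(w, labels) == pytest.approx(q_oracle, abs=1e-12)


class TestDetectCommunities:
    def test_homogeneous_clique_single_community(self):
        w = np.ones((8, 8))
        part = detect_communities(w, seed=0, n_init=5)
        assert part.n_communities == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_planted_three_blocks_recovered(self, rng):
        # planted-partition similarity: within 0.9, across 0.1, 20 per block
        truth = np.repeat(np.arange(3), 20)
        w = np.where(truth[:, None] == truth[None, :], 0.9, 0.1)
        w += rng.normal(size=w.shape) * 0.01
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        part = detect_communities(w, seed=0, n_init=10)
        assert adjusted_rand_score(truth, part.communities) == 1.0

    def test_attains_exhaustive_maximum_on_small_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            w = rng.random((n, n))
            w = (w + w.T) / 2 - 0.2
            np.fill_diagonal(w, 0.0)
            part = detect_communities(w, seed=3, n_init=30)
            best = max(modularity(w, np.array(p)) for p in all_partitions(n))
            assert part.Q == pytest.approx(best, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        w = np.abs(rng.normal(size=(20, 20)))
        w = (w + w.T) / 2
        p1 = detect_communities(w, seed=5, n_init=5)
        p2 = detect_communities(w, seed=5, n_init=5)
        np.testing.assert_array_equal(p1.communities, p2.communities)

    def test_edgeless_graph_single_community_with_warning(self):
        w = -np.ones((5, 5))
        with pytest.warns(UserWarning, match="single"):
            part = detect_communities(w, seed=0)
        assert part.n_communities == 1
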