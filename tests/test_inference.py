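"""Splits, duration matching, cluster permutation, latency estimation."""

import numpy as np
import pandas as pd
import pytest

from syntrf.inference import (
    Adjacency,
    cluster_perm,
    duration_match,
    median_split,
    random_split,
    xcorr_latency,
)


def events_from(values, key="surprisal_trigram"):
    return pd.DataFrame({key: values})


class TestMedianSplit:
    def test_even_split(self):
        low, high = median_split(events_from([1, 2, 3, 4]), "surprisal_trigram")
        assert sorted(low.surprisal_trigram) == [1, 2]
        assert sorted(high.surprisal_trigram) == [3, 4]

    def test_ties_go_low(self):
        low, high = median_split(events_from([1, 2, 2, 3]), "surprisal_trigram")
        assert sorted(low.surprisal_trigram) == [1, 2, 2]
        assert sorted(high.surprisal_trigram) == [3]

    def test_resplitting_low_partitions_it(self):
        low, _ = median_split(events_from([1, 2, 3, 4, 5, 6]),
                              "surprisal_trigram")
        ll, lh = median_split(low, "surprisal_trigram")
        assert len(ll) + len(lh) == len(low)
        assert set(ll.index) | set(lh.index) == set(low.index)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            median_split(events_from([2, 2, 2]), "surprisal_trigram")


class TestRandomSplit:
    def test_half_sizes_and_determinism(self):
        ev = events_from(np.arange(100))
        a, b = random_split(ev, 5)
        assert len(a) == len(b) == 50
        a2, b2 = random_split(ev, 5)
        assert list(a.index) == list(a2.index)

    def test_odd_count(self):
        a, b = random_split(events_from(np.arange(7)), 0)
        assert abs(len(a) - len(b)) <= 1

    def test_seeds_differ(self):
        ev = events_from(np.arange(60))
        base = set(random_split(ev, 0)[0].index)
        assert any(
            set(random_split(ev, s)[0].index) != base for s in range(1, 11)
        )


class TestDurationMatch:
    def test_overlap_worked_example(self):
        # one bin with 100 high and 150 low -> 100 kept per condition
        low = pd.DataFrame({"duration": np.full(150, 0.205)})
        high = pd.DataFrame({"duration": np.full(100, 0.205)})
        ml, mh = duration_match(low, high, seed=0)
        assert len(ml) == len(mh) == 100

    def test_identical_lists_fully_kept(self, rng):
        d = rng.uniform(0.05, 1.0, 200)
        low = pd.DataFrame({"duration": d})
        high = pd.DataFrame({"duration": d.copy()})
        ml, mh = duration_match(low, high, seed=1)
        assert len(ml) == len(mh) == 200

    def test_disjoint_ranges_error(self):
        low = pd.DataFrame({"duration": np.full(20, 0.1)})
        high = pd.DataFrame({"duration": np.full(20, 0.9)})
        with pytest.raises(ValueError):
            duration_match(low, high)

    def test_histograms_identical_and_deterministic(self, rng):
        low = pd.DataFrame({"duration": rng.uniform(0.05, 0.8, 400)})
        high = pd.DataFrame({"duration": rng.uniform(0.1, 1.0, 300)})
        ml, mh = duration_match(low, high, seed=9)
        edges = np.linspace(0, 1.25, 101)
        hl = np.histogram(ml.duration, edges)[0]
        hh = np.histogram(mh.duration, edges)[0]
        assert np.array_equal(hl, hh)
        ml2, _ = duration_match(low, high, seed=9)
        assert list(ml.index) == list(ml2.index)

    def test_out_of_range_dropped_with_warning(self):
        low = pd.DataFrame({"duration": [0.2, 0.2, 2.0]})
        high = pd.DataFrame({"duration": [0.2, 0.2]})
        with pytest.warns(UserWarning):
            ml, mh = duration_match(low, high, seed=0)
        assert len(ml) == len(mh) == 2


class TestClusterPerm:
    def test_identical_conditions_no_clusters(self, rng):
        adj = Adjacency.grid(8)
        A = rng.normal(size=(10, 8, 20))
        res = cluster_perm(A, A.copy(), adj, n_perm=100, seed=0)
        assert len(res.clusters) == 0

    def test_planted_effect_found(self, rng):
        adj = Adjacency.grid(16)
        S, C, T = 24, 16, 50
        A = rng.normal(size=(S, C, T))
        B = rng.normal(size=(S, C, T))
        region_ch = [0, 1, 4, 5]        # a connected grid neighborhood
        A[:, region_ch, 10:35] += 3.0
        res = cluster_perm(A, B, adj, n_perm=500, seed=1)
        assert res.p_values[0] < 0.05
        planted = {c * T + t for c in region_ch for t in range(10, 35)}
        covered = planted & set(res.clusters[0].tolist())
        assert len(covered) >= 0.8 * len(planted)

    def test_swap_negates_masses(self, rng):
        adj = Adjacency.grid(4)
        A = rng.normal(size=(12, 4, 15))
        B = rng.normal(size=(12, 4, 15)) + 0.5
        r1 = cluster_perm(A, B, adj, n_perm=200, seed=3)
        r2 = cluster_perm(B, A, adj, n_perm=200, seed=3)
        assert np.allclose(np.sort(r1.masses), np.sort(-r2.masses))

    def test_time_free_maps_accepted(self, rng):
        adj = Adjacency.grid(9)
        A = rng.normal(size=(10, 9))
        B = rng.normal(size=(10, 9))
        res = cluster_perm(A, B, adj, n_perm=100, seed=0)
        assert res.t_map.shape == (9, 1)

    def test_adjacency_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_perm(rng.normal(size=(6, 5, 4)),
                         rng.normal(size=(6, 5, 4)),
                         Adjacency.grid(8), n_perm=10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_perm(rng.normal(size=(1, 4, 4)),
                         rng.normal(size=(1, 4, 4)),
                         Adjacency.grid(4), n_perm=10)


class TestAdjacency:
    def test_grid_is_symmetric_no_self_loops(self):
        adj = Adjacency.grid(12)
        for c, ns in adj.neighbors.items():
            assert c not in ns
            for n in ns:
                assert c in adj.neighbors[n]

    def test_json_round_trip(self):
        adj = Adjacency.grid(6)
        adj2 = Adjacency.from_json(adj.to_json())
        assert adj2.neighbors == adj.neighbors

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            Adjacency(channels=["a", "b"],
                      neighbors={"a": {"b"}, "b": set()})


def bump(T, center, width=8.0):
    t = np.arange(T)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestXcorrLatency:
    fs = 200.0

    def test_constructed_shift_recovered(self):
        T, C = 241, 6
        low = np.stack([bump(T, 60 + 5 * c) for c in range(C)])
        high = np.stack([np.roll(low[c], 30) for c in range(C)])
        res = xcorr_latency(low, high, range(C), self.fs, n_null=200, seed=0)
        assert res.modal_lag == pytest.approx(0.150)
        assert res.mean_corr > 0.999

    def test_identical_waveforms(self):
        low = np.stack([bump(241, 80), bump(241, 120)])
        res = xcorr_latency(low, low.copy(), [0, 1], self.fs, n_null=100,
                            seed=0)
        assert res.modal_lag == 0.0
        assert res.mean_corr == pytest.approx(1.0)

    def test_antisymmetry(self):
        T, C = 241, 4
        low = np.stack([bump(T, 70 + 3 * c) for c in range(C)])
        high = np.stack([np.roll(low[c], 24) for c in range(C)])
        r1 = xcorr_latency(low, high, range(C), self.fs, n_null=50, seed=0)
        r2 = xcorr_latency(high, low, range(C), self.fs, n_null=50, seed=0)
        assert r1.modal_lag == -r2.modal_lag

    def test_zero_channel_dropped_with_warning(self):
        low = np.stack([bump(100, 40), np.zeros(100)])
        high = np.stack([np.roll(low[0], 10), np.zeros(100)])
        with pytest.warns(UserWarning):
            res = xcorr_latency(low, high, [0, 1], self.fs, n_null=50, seed=0)
        assert list(res.channels) == [0]

    def test_planted_shift_p_small(self, rng):
        T, C = 241, 12
        low = np.stack([bump(T, 60 + 2 * c) + 0.05 * rng.normal(size=T)
                        for c in range(C)])
        high = np.stack([np.roll(low[c], 30) for c in range(C)])
        res = xcorr_latency(low, high, range(C), self.fs, n_null=1000, seed=2)
        assert res.p_value < 0.05
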