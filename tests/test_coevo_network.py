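import math
from collections import deque

import numpy as np
import pytest

from coevomap.coevo_network import (
    BAND_LOW,
    BAND_MID,
    BAND_TOP,
    build_network,
    cumulative_mi,
    filter_network,
    neighborhood,
    percentile_bands,
    proximity_mi,
)
from coevomap.mi_engine import ScoreMatrices
from coevomap.structure_map import SeqStructMap


def scores_from_z(z, positions=None):
    z = np.asarray(z, dtype=float)
    k = z.shape[0]
    if positions is None:
        positions = np.arange(1, k + 1)
    np.fill_diagonal(z, np.nan)
    return ScoreMatrices(
        mi_raw=np.zeros_like(z), mi_apc=np.zeros_like(z), z=z,
        degenerate=np.zeros_like(z, dtype=bool),
        positions=np.asarray(positions), mean_mi=0.0,
        n_permutations=2, seed=0,
    )


def z_matrix_from_pairs(k, pairs):
    z = np.zeros((k, k))
    for i, j, v in pairs:
        z[i, j] = z[j, i] = v
    return z


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        z = z_matrix_from_pairs(4, [(0, 1, 7.0), (1, 2, 6.4), (2, 3, 6.5)])
        g = build_network(scores_from_z(z), threshold=6.5)
        assert g.number_of_edges() == 1
        assert g.has_edge(1, 2)  # positions are 1-based
        assert g.number_of_nodes() == 4  # isolated positions retained

    def test_empty_edge_set_keeps_nodes(self):
        z = z_matrix_from_pairs(5, [(0, 1, 2.0)])
        g = build_network(scores_from_z(z), threshold=6.5)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_node_attributes_attached(self):
        z = z_matrix_from_pairs(3, [(0, 1, 8.0)])
        g = build_network(scores_from_z(z, positions=[4, 9, 12]), threshold=6.5,
                          conservation=[0.5, 1.5, 2.5], reference_aa=list("ACD"))
        assert g.nodes[9]["aa"] == "C"
        assert g.nodes[12]["kl"] == 2.5
        assert g.edges[4, 9]["separation"] == 5


class TestCumulativeMi:
    def test_sums_only_retained_edges(self):
        z = z_matrix_from_pairs(4, [(0, 1, 7.0), (0, 2, 8.5), (0, 3, 6.0)])
        g = build_network(scores_from_z(z), threshold=6.5)
        cmi = cumulative_mi(g)
        assert cmi[1] == pytest.approx(15.5)
        assert cmi[4] == 0.0  # isolated node

    def test_handshake_identity(self):
        rng = np.random.default_rng(77)
        z = rng.uniform(0, 12, (10, 10))
        z = (z + z.T) / 2
        g = build_network(scores_from_z(z), threshold=6.5)
        cmi = cumulative_mi(g)
        total_z = sum(d["z"] for _, _, d in g.edges(data=True))
        assert sum(cmi.values()) == pytest.approx(2 * total_z)

    def test_matches_brute_force_incidence_sum(self):
        rng = np.random.default_rng(78)
        z = rng.uniform(0, 10, (8, 8))
        z = (z + z.T) / 2
        g = build_network(scores_from_z(z), threshold=5.0)
        cmi = cumulative_mi(g)
        for node in g.nodes:
            expected = sum(g.edges[node, other]["z"] for other in g.neighbors(node))
            assert cmi[node] == pytest.approx(expected)


class TestProximityMi:
    def _network_with_cmi(self, cmi_values):
        k = len(cmi_values)
        g = build_network(scores_from_z(np.zeros((k, k))), threshold=6.5)
        for node, value in zip(sorted(g.nodes), cmi_values):
            g.nodes[node]["cmi"] = value
        return g

    def test_mean_of_neighbors_within_radius(self):
        g = self._network_with_cmi([5.0, 10.0, 20.0, 30.0])
        smap = SeqStructMap(column_to_residue={0: 0, 1: 1, 2: 2, 3: 3},
                            coverage=1.0,
                            author_numbers={0: "1", 1: "2", 2: "3", 3: "4"})
        d = np.array([
            [0.0, 4.0, 4.5, 5.0],
            [4.0, 0.0, 9.0, 9.0],
            [4.5, 9.0, 0.0, 9.0],
            [5.0, 9.0, 9.0, 0.0],
        ])
        pmi = proximity_mi(g, smap, d, radius=5.0)
        # node 1's neighbors within <=5: cMI 10, 20, 30 -> mean 20; radius inclusive
        assert pmi[1] == pytest.approx(20.0)
        assert g.nodes[1]["pmi"] == pytest.approx(20.0)
        assert g.nodes[1]["pdb_number"] == "1"

    def test_no_neighbor_within_radius_is_missing(self):
        g = self._network_with_cmi([1.0, 2.0])
        smap = SeqStructMap(column_to_residue={0: 0, 1: 1}, coverage=1.0)
        d = np.array([[0.0, 50.0], [50.0, 0.0]])
        pmi = proximity_mi(g, smap, d, radius=5.0)
        assert math.isnan(pmi[1]) and math.isnan(pmi[2])

    def test_unmapped_positions_are_missing(self):
        g = self._network_with_cmi([1.0, 2.0, 3.0])
        smap = SeqStructMap(column_to_residue={0: 0, 2: 1}, coverage=0.7)
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        pmi = proximity_mi(g, smap, d, radius=5.0)
        assert math.isnan(pmi[2])          # column 1 not mapped
        assert pmi[1] == pytest.approx(3.0)

    def test_include_self_flag(self):
        g = self._network_with_cmi([10.0, 30.0])
        smap = SeqStructMap(column_to_residue={0: 0, 1: 1}, coverage=1.0)
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert proximity_mi(g, smap, d, radius=5.0)[1] == pytest.approx(30.0)
        assert proximity_mi(g, smap, d, radius=5.0,
                            include_self=True)[1] == pytest.approx(20.0)

    def test_matches_brute_force_neighborhood_oracle(self):
        from coevomap.synth_fixtures import helix_ca_coordinates

        coords = helix_ca_coordinates(12)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        rng = np.random.default_rng(9)
        cmi_vals = rng.uniform(0, 20, 12)
        g = self._network_with_cmi(cmi_vals)
        smap = SeqStructMap(column_to_residue={i: i for i in range(12)}, coverage=1.0)
        pmi = proximity_mi(g, smap, d, radius=5.0)
        for node in g.nodes:
            i = node - 1
            vals = [cmi_vals[j] for j in range(12) if j != i and d[i, j] <= 5.0]
            if vals:
                assert pmi[node] == pytest.approx(np.mean(vals))
            else:
                assert math.isnan(pmi[node])


class TestPercentileBands:
    def _network_with_edge_z(self, zvals):
        k = len(zvals) + 1
        pairs = [(0, i + 1, 7.0 + zv) for i, zv in enumerate(zvals)]
        # build via z matrix so edges carry the requested z above threshold 6.5
        z = z_matrix_from_pairs(k, [(i, j, v) for i, j, v in pairs])
        return build_network(scores_from_z(z), threshold=6.5)

    def test_100_distinct_edges_split_5_25_70(self):
        g = self._network_with_edge_z(list(np.linspace(0.1, 10.0, 100)))
        bands = list(percentile_bands(g).values())
        assert bands.count(BAND_TOP) == 5
        assert bands.count(BAND_MID) == 25
        assert bands.count(BAND_LOW) == 70

    def test_all_equal_z_promotes_everything_to_top(self):
        g = self._network_with_edge_z([1.0] * 10)
        assert set(percentile_bands(g).values()) == {BAND_TOP}

    def test_20_distinct_edges_have_one_top(self):
        g = self._network_with_edge_z(list(np.linspace(0.1, 2.0, 20)))
        assert list(percentile_bands(g).values()).count(BAND_TOP) == 1

    def test_single_edge_is_top(self):
        g = self._network_with_edge_z([1.0])
        assert list(percentile_bands(g).values()) == [BAND_TOP]

    def test_bands_are_ordered_by_z(self):
        rng = np.random.default_rng(3)
        g = self._network_with_edge_z(list(rng.uniform(0, 5, 40)))
        bands = percentile_bands(g)
        by_band = {BAND_TOP: [], BAND_MID: [], BAND_LOW: []}
        for (u, v), band in bands.items():
            by_band[band].append(g.edges[u, v]["z"])
        assert min(by_band[BAND_TOP]) >= max(by_band[BAND_MID])
        assert min(by_band[BAND_MID]) >= max(by_band[BAND_LOW])

    def test_empty_network_rejected(self):
        g = build_network(scores_from_z(np.zeros((3, 3))), threshold=6.5)
        with pytest.raises(ValueError):
            percentile_bands(g)


class TestFilterNetwork:
    def _random_network(self, seed=4, k=12):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 12, (k, k))
        z = (z + z.T) / 2
        g = build_network(scores_from_z(z), threshold=6.5,
                          conservation=list(rng.uniform(0, 3, k)))
        return g

    def test_top_n_with_n_at_least_edge_count_is_identity_on_edges(self):
        g = self._random_network()
        sub = filter_network(g, top_n=g.number_of_edges() + 5)
        assert set(sub.edges) == set(g.edges)

    def test_top_n_keeps_highest_z(self):
        g = self._random_network()
        sub = filter_network(g, top_n=3)
        kept = sorted((d["z"] for _, _, d in sub.edges(data=True)), reverse=True)
        all_z = sorted((d["z"] for _, _, d in g.edges(data=True)), reverse=True)
        assert kept == all_z[:3]
        assert all(sub.degree(n) > 0 for n in sub.nodes)

    def test_separation_filter_can_empty_the_edge_set(self):
        z = z_matrix_from_pairs(5, [(i, i + 1, 8.0) for i in range(4)])
        g = build_network(scores_from_z(z), threshold=6.5)
        sub = filter_network(g, separation=(2, None))
        assert sub.number_of_edges() == 0

    def test_cmi_filter_matches_brute_force_scan(self):
        g = self._random_network(seed=8)
        cutoff = float(np.median([d["cmi"] for _, d in g.nodes(data=True)]))
        sub = filter_network(g, cmi=(cutoff, None))
        expected = {n for n, d in g.nodes(data=True) if d["cmi"] >= cutoff}
        assert set(sub.nodes) == expected

    def test_contradictory_ranges_give_empty_network(self):
        g = self._random_network()
        sub = filter_network(g, kl=(10.0, 5.0))
        assert sub.number_of_nodes() == 0

    def test_node_filter_commutes_with_neighborhood(self):
        g = self._random_network(seed=10)
        node = max(g.nodes, key=lambda n: g.degree(n))
        cutoff = float(np.percentile([d["kl"] for _, d in g.nodes(data=True)], 30))
        a = filter_network(neighborhood(g, node, "first_neighbors"), kl=(cutoff, None))
        filtered = filter_network(g, kl=(cutoff, None))
        if node in filtered:
            b = neighborhood(filtered, node, "first_neighbors")
            assert set(a.nodes) == set(b.nodes)
            assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))


class TestNeighborhood:
    def test_isolated_node_first_neighbors_is_itself(self):
        g = build_network(scores_from_z(np.zeros((4, 4))), threshold=6.5)
        sub = neighborhood(g, 2, "first_neighbors")
        assert set(sub.nodes) == {2}

    def test_triangle_component_is_whole_triangle(self):
        z = z_matrix_from_pairs(5, [(0, 1, 8.0), (1, 2, 8.0), (0, 2, 8.0)])
        g = build_network(scores_from_z(z), threshold=6.5)
        sub = neighborhood(g, 1, "connected_component")
        assert set(sub.nodes) == {1, 2, 3}

    def test_component_matches_bfs_oracle(self):
        rng = np.random.default_rng(5)
        z = (rng.uniform(0, 10, (15, 15)) > 8).astype(float) * 9.0
        z = np.maximum(z, z.T)
        g = build_network(scores_from_z(z), threshold=6.5)
        start = 1
        seen = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        sub = neighborhood(g, start, "connected_component")
        assert set(sub.nodes) == seen

    def test_unknown_node_and_mode_rejected(self):
        g = build_network(scores_from_z(np.zeros((3, 3))), threshold=6.5)
        with pytest.raises(KeyError):
            neighborhood(g, 99)
        with pytest.raises(ValueError):
            neighborhood(g, 1, "bogus")
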