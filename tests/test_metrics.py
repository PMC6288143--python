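"""Complex-network metrics against brute-force oracles and simulations."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pytest
from scipy.stats import zipf

from bandnet import (
    VoxelGraph,
    atlas_coverage,
    average_clustering,
    characteristic_path_length,
    default_delta,
    degree_distribution,
    degree_preserving_rewire,
    fit_power_law,
    generate_atlas,
    hub_vertices,
    network_difference_test,
    region_connectivity_matrix,
    small_world_indices,
)
from bandnet.network import scan_order_coords

from conftest import random_voxel_graph


def from_nx(g):
    return VoxelGraph.from_networkx(g)


def brute_clustering(g: VoxelGraph) -> float:
    adj = {i: set() for i in range(g.n_vertices)}
    for i, j in g.edges:
        adj[i].add(j)
        adj[j].add(i)
    vals = []
    for v in range(g.n_vertices):
        k = len(adj[v])
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        vals.append(tri / (k * (k - 1) / 2))
    return float(np.mean(vals))


def brute_path_length(g: VoxelGraph):
    adj = {i: set() for i in range(g.n_vertices)}
    for i, j in g.edges:
        adj[i].add(j)
        adj[j].add(i)
    dists = []
    n_pairs = 0
    for s in range(g.n_vertices):
        seen = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in range(s + 1, g.n_vertices):
            n_pairs += 1
            if t in seen:
                dists.append(seen[t])
    return float(np.mean(dists)), len(dists) / n_pairs


class TestClusteringAndPathLength:
    def test_complete_graph_clustering_is_one(self):
        assert average_clustering(from_nx(nx.complete_graph(4))) == 1.0

    def test_star_graph_clustering_is_zero(self):
        assert average_clustering(from_nx(nx.star_graph(4))) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clustering_matches_triangle_enumeration(self, seed):
        g = random_voxel_graph(np.random.default_rng(seed), n=12, p=0.35)
        assert np.isclose(average_clustering(g), brute_clustering(g), atol=1e-12)

    def test_path_graph_p3(self):
        res = characteristic_path_length(from_nx(nx.path_graph(3)))
        assert np.isclose(res.length, 4.0 / 3.0)
        assert res.connected_pair_fraction == 1.0

    def test_complete_graph_path_length_is_one(self):
        assert characteristic_path_length(from_nx(nx.complete_graph(6))).length == 1.0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_path_length_matches_bfs_oracle(self, seed):
        g = random_voxel_graph(np.random.default_rng(seed), n=15, p=0.2)
        L, frac = brute_path_length(g)
        res = characteristic_path_length(g)
        assert np.isclose(res.length, L)
        assert np.isclose(res.connected_pair_fraction, frac)

    def test_empty_graph_rejected(self):
        g = VoxelGraph(3, scan_order_coords(3), frozenset())
        with pytest.raises(ValueError, match="empty graph"):
            characteristic_path_length(g)


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        g = random_voxel_graph(rng, n=20, p=0.25)
        r = degree_preserving_rewire(g, seed=1)
        assert sorted(g.degrees()) == sorted(r.degrees())
        assert np.array_equal(g.degrees(), r.degrees())  # per-vertex, not just multiset

    def test_same_seed_same_output(self, rng):
        g = random_voxel_graph(rng, n=20, p=0.25)
        assert degree_preserving_rewire(g, seed=5).edges == degree_preserving_rewire(g, seed=5).edges

    def test_ring_lattice_clustering_drops_to_er_level(self):
        """Rewiring a clustered ring lattice drives C toward the random
        expectation k/(n-1)."""
        ring = nx.watts_strogatz_graph(100, 8, 0.0, seed=0)  # pure lattice, C = 0.643
        g = from_nx(ring)
        c0 = average_clustering(g)
        r = degree_preserving_rewire(g, seed=2)
        c1 = average_clustering(r)
        er = 8 / 99
        assert c0 > 0.6
        assert c1 < 0.25
        assert abs(c1 - er) < 0.06

    def test_no_legal_swap_warns_and_returns_input(self):
        g = from_nx(nx.complete_graph(4))  # no swap can avoid multi-edges
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = degree_preserving_rewire(g, seed=0)
        assert out.edges == g.edges
        assert any("rewire" in str(w.message) or "swap" in str(w.message) for w in rec)


class TestSmallWorld:
    def test_watts_strogatz_graph_is_small_world(self):
        ws = nx.connected_watts_strogatz_graph(200, 10, 0.1, seed=42)
        gm = small_world_indices(from_nx(ws), n_random=10, seed=1)
        assert gm.gamma > 1.0
        assert gm.sigma > 1.0

    def test_sigma_lambda_gamma_identity(self):
        ws = nx.connected_watts_strogatz_graph(100, 8, 0.2, seed=3)
        gm = small_world_indices(from_nx(ws), n_random=3, seed=1)
        assert np.isclose(gm.sigma * gm.lambda_ratio, gm.gamma, rtol=1e-12)
        assert np.isclose(gm.gamma, gm.clustering_C / gm.C_random, rtol=1e-12)
        assert np.isclose(gm.lambda_ratio, gm.path_length_L / gm.L_random, rtol=1e-12)

    def test_rewired_graph_against_own_ensemble_is_not_small_world(self):
        """A degree-preserving randomisation scored against its own ensemble
        has sigma ~ 1 (dense enough that clustering concentrates)."""
        ws = nx.connected_watts_strogatz_graph(200, 20, 0.1, seed=42)
        g = from_nx(ws)
        null = degree_preserving_rewire(g, n_swaps=30 * g.n_edges, seed=7)
        gm = small_world_indices(null, n_random=20, seed=2)
        assert abs(gm.sigma - 1.0) < 0.1


class TestPowerLaw:
    def test_exponent_recovery_on_zipf_samples(self):
        alpha = 2.5
        draws = zipf.rvs(alpha, size=5000, random_state=7)
        fit = fit_power_law(draws)
        assert fit.fitted
        assert abs(fit.exponent - alpha) < 0.2

    def test_constant_degrees_refused(self):
        g = from_nx(nx.cycle_graph(30))  # all degree 2
        fit = fit_power_law(degree_distribution(g))
        assert not fit.fitted
        assert "distinct" in fit.reason

    def test_poisson_degrees_fit_worse_than_power_law(self):
        rngs = np.random.default_rng(5)
        pl = zipf.rvs(2.5, size=3000, random_state=5)
        poisson = rngs.poisson(20.0, size=3000) + 1
        fit_pl = fit_power_law(pl)
        fit_po = fit_power_law(poisson)
        assert fit_pl.fitted and fit_po.fitted
        assert fit_pl.ks_distance < fit_po.ks_distance


class TestHubsAndAtlas:
    def test_star_center_is_the_hub(self):
        assert hub_vertices(from_nx(nx.star_graph(5)), k=1) == [0]

    def test_k_equals_n_returns_everything(self, rng):
        g = random_voxel_graph(rng, n=10)
        assert sorted(hub_vertices(g, k=10)) == list(range(10))

    def test_agrees_with_full_sort_oracle(self, rng):
        g = random_voxel_graph(rng, n=25, p=0.3)
        deg = g.degrees()
        oracle = sorted(range(25), key=lambda v: (-deg[v], v))[:5]
        assert hub_vertices(g, k=5) == oracle

    def test_coverage_full_when_hubs_sit_on_centers(self):
        atlas = generate_atlas(90)
        cov = atlas_coverage(atlas.centers, atlas, delta=0.5)
        assert cov.matched_regions_M == 90
        assert cov.accuracy_A == 1.0

    def test_coverage_zero_when_no_hub_in_range(self):
        atlas = generate_atlas(27, bounding_box=((0, 0, 0), (3, 3, 3)))
        cov = atlas_coverage(np.array([[100.0, 100.0, 100.0]]), atlas, delta=1.0)
        assert cov.accuracy_A == 0.0

    def test_two_hubs_near_one_center_counted_once(self):
        atlas = generate_atlas(8, bounding_box=((0, 0, 0), (4, 4, 4)))
        c = atlas.centers[0]
        hubs = np.vstack([c + 0.01, c - 0.01])
        cov = atlas_coverage(hubs, atlas, delta=0.1)
        assert cov.matched_regions_M == 1

    def test_default_delta_is_half_mean_nn_distance(self):
        atlas = generate_atlas(8, bounding_box=((0, 0, 0), (4, 4, 4)))
        assert np.isclose(default_delta(atlas), 1.0)  # spacing 2 -> nn 2 -> half 1


class TestRegionMatrix:
    def test_single_region_collects_all_edges(self, rng):
        g = random_voxel_graph(rng, n=10, p=0.4)
        atlas = generate_atlas(1)
        rcm = region_connectivity_matrix(g, atlas, delta=1000.0)
        assert rcm.counts[0, 0] == g.n_edges

    def test_bipartite_edges_land_off_diagonal(self):
        coords = np.array(
            [[0.0, 0, 0], [0.2, 0, 0], [5.0, 0, 0], [5.2, 0, 0]]
        )
        g = VoxelGraph(4, coords, frozenset({(0, 2), (0, 3), (1, 2)}))
        from bandnet import RegionAtlas

        atlas = RegionAtlas(centers=np.array([[0.1, 0, 0], [5.1, 0, 0]]), names=["a", "b"])
        rcm = region_connectivity_matrix(g, atlas, delta=1.0)
        assert rcm.counts[0, 1] == 3 and rcm.counts[1, 0] == 3
        assert rcm.counts[0, 0] == 0 and rcm.counts[1, 1] == 0

    def test_matches_per_edge_tally_and_conserves_mass(self, rng):
        g = random_voxel_graph(rng, n=30, p=0.25)
        atlas = generate_atlas(3, bounding_box=((0, 0, 0), (4, 4, 4)))
        rcm = region_connectivity_matrix(g, atlas)
        # brute-force tally
        from scipy.spatial.distance import cdist

        assign = cdist(g.vertex_coords, atlas.centers).argmin(axis=1)
        expect = np.zeros((3, 3), dtype=int)
        for i, j in g.edges:
            a, b = sorted((assign[i], assign[j]))
            expect[a, b] += 1
        expect = expect + np.triu(expect, 1).T
        assert np.array_equal(rcm.counts, expect)
        assert rcm.total_edges == g.n_edges


class TestDifferenceTest:
    @pytest.mark.parametrize("stat", ["jaccard", "degree_ks"])
    def test_identical_graphs_give_p_one(self, rng, stat):
        g = random_voxel_graph(rng, n=15, p=0.3)
        res = network_difference_test(g, g, statistic=stat, n_perm=199, seed=0)
        assert res.p_value == 1.0

    def test_identical_graphs_region_statistic_p_one(self, rng):
        g = random_voxel_graph(rng, n=15, p=0.3)
        atlas = generate_atlas(3, bounding_box=((0, 0, 0), (3, 3, 3)))
        res = network_difference_test(
            g, g, statistic="region_frobenius", n_perm=99, seed=0, atlas=atlas
        )
        assert res.p_value == 1.0

    def test_dense_vs_sparse_detected(self):
        rng = np.random.default_rng(0)
        dense = random_voxel_graph(rng, n=40, p=0.4)
        sparse = random_voxel_graph(rng, n=40, p=0.1)
        res = network_difference_test(dense, sparse, "degree_ks", n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_p_floor_is_add_one(self, rng):
        g = random_voxel_graph(rng, n=20, p=0.3)
        h = random_voxel_graph(rng, n=20, p=0.3)
        res = network_difference_test(g, h, "degree_ks", n_perm=199, seed=2)
        assert 1.0 / 200 <= res.p_value <= 1.0

    def test_low_n_perm_warns(self, rng):
        g = random_voxel_graph(rng, n=10)
        with pytest.warns(UserWarning, match="resolution"):
            network_difference_test(g, g, "jaccard", n_perm=20, seed=0)
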