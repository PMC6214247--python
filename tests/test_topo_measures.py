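import math

import networkx as nx
import numpy as np
import pytest

from painmark import (
    Connectome,
    GraphMetrics,
    MeasureConfig,
    NullEnsembleConfig,
    average_clustering_coefficient,
    average_closeness_centrality,
    average_edge_betweenness,
    average_efficiency,
    average_node_betweenness,
    average_node_degree,
    average_radiality,
    characteristic_path_length,
    cn_lcl_arrays,
    lattice_equivalent,
    lcp_correlation,
    measure_all,
    modularity,
    modularity_of_partition,
    power_law_pvalue,
    power_lawness,
    random_equivalent,
    smallworldness_omega,
    smallworldness_sigma,
    stability_check,
    structural_consistency,
)
from painmark.topo_measures import _sample_discrete_pl
from conftest import make_connectome
import oracles


def from_nx(g):
    a = nx.to_numpy_array(g)
    ids = [f"n{k}" for k in range(g.number_of_nodes())]
    return Connectome(a, ids, {v: "S1" for v in ids}, binary=True)


def connected_er(n, m, seed):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return from_nx(g)


class TestHandExamples:
    def test_average_node_degree(self, k3, path3):
        assert average_node_degree(k3) == 2
        assert average_node_degree(path3) == pytest.approx(4 / 3)

    def test_handshake_identity(self):
        rng = np.random.default_rng(3)
        c = connected_er(12, 25, 3)
        assert average_node_degree(c) == pytest.approx(2 * c.n_edges / c.n_nodes)

    def test_characteristic_path_length(self, k3, path4):
        assert characteristic_path_length(k3) == 1
        assert characteristic_path_length(path4) == pytest.approx(10 / 6)

    def test_average_efficiency(self, k3, path4):
        assert average_efficiency(k3) == 1
        assert average_efficiency(path4) == pytest.approx(13 / 18)

    def test_efficiency_of_isolated_nodes_is_zero(self):
        c = make_connectome([], 2)
        assert average_efficiency(c) == 0.0

    def test_clustering(self, k3, star4):
        assert average_clustering_coefficient(k3) == 1
        assert average_clustering_coefficient(star4) == 0

    def test_closeness(self, k3, star4, path3):
        assert average_closeness_centrality(k3) == 1
        assert average_closeness_centrality(star4) == pytest.approx(0.7)
        assert average_closeness_centrality(path3) == pytest.approx(7 / 9)

    def test_node_betweenness(self, k3, path3, star4):
        assert average_node_betweenness(k3) == 0
        assert average_node_betweenness(path3) == pytest.approx(1 / 3)
        assert average_node_betweenness(star4) == pytest.approx(0.75)

    def test_edge_betweenness(self, k3, path3):
        assert average_edge_betweenness(k3) == pytest.approx(1)
        assert average_edge_betweenness(path3) == pytest.approx(2)

    def test_radiality(self, path3, star4, k3):
        assert average_radiality(path3) == pytest.approx(10 / 3)
        assert average_radiality(star4) == pytest.approx(4.5)
        assert average_radiality(k3) is None  # diameter 1: undefined

    def test_measures_require_binarized_input(self):
        c = make_connectome([(0, 1)], 2, binary=False, weights=[0.5])
        with pytest.raises(ValueError, match="binarized"):
            average_node_degree(c)

    def test_cpl_error_when_no_pair_connected(self):
        c = make_connectome([], 3)
        with pytest.raises(ValueError):
            characteristic_path_length(c)


class TestLocalCommunityParadigm:
    def test_k4_every_edge_cn2_lcl1(self, k4):
        per_edge = oracles.oracle_cn_lcl(k4.adjacency)
        cn, lcl = cn_lcl_arrays(k4)
        assert sorted(zip(cn, lcl)) == sorted(per_edge.values())
        assert list(cn) == [2] * 6 and list(lcl) == [1] * 6

    def test_path_has_no_qualifying_edges(self, path3):
        cn, lcl = cn_lcl_arrays(path3)
        assert cn.size == 0 and lcl.size == 0

    def test_f6_worked_example(self, f6):
        cn, lcl = cn_lcl_arrays(f6)
        assert sorted(cn) == [2, 2, 2, 2, 2, 2, 3, 3, 3]
        assert sorted(lcl) == [1, 1, 1, 1, 1, 1, 2, 2, 2]
        # per-edge agreement with brute-force common-neighbour enumeration
        per_edge = oracles.oracle_cn_lcl(f6.adjacency)
        got = dict(zip(map(tuple, f6.edge_index_pairs()), zip(cn, lcl)))
        got = {e: v for e, v in got.items() if e in per_edge}
        assert got == per_edge
        assert lcp_correlation(f6) == pytest.approx(1.0)

    def test_k4_has_constant_arrays_hence_undefined(self, k4):
        assert lcp_correlation(k4) is None

    def test_relabeling_invariance(self):
        c = connected_er(12, 30, 7)
        perm = np.random.default_rng(1).permutation(12)
        a2 = c.adjacency[np.ix_(perm, perm)]
        c2 = Connectome(a2, c.node_ids, c.region_of, binary=True)
        v1, v2 = lcp_correlation(c), lcp_correlation(c2)
        if v1 is None:
            assert v2 is None
        else:
            assert v1 == pytest.approx(v2)


@pytest.fixture(scope="module")
def atlas():
    return oracles.connected_atlas_graphs(max_n=6)


class TestDeterministicOracleEquivalence:
    """All nine deterministic measures vs explicit enumeration, n <= 6."""

    def test_all_connected_graphs_up_to_n6(self, atlas):
        assert len(atlas) > 100  # 2..6 nodes: 142 connected graphs
        for a in atlas:
            ids = [f"n{k}" for k in range(a.shape[0])]
            c = Connectome(a, ids, {v: "S1" for v in ids}, binary=True)
            assert average_node_degree(c) == pytest.approx(oracles.oracle_and(a))
            assert characteristic_path_length(c) == pytest.approx(oracles.oracle_cpl(a))
            assert average_efficiency(c) == pytest.approx(oracles.oracle_ae(a))
            assert average_clustering_coefficient(c) == pytest.approx(oracles.oracle_acc(a))
            assert average_closeness_centrality(c) == pytest.approx(oracles.oracle_acce(a))
            assert average_node_betweenness(c) == pytest.approx(oracles.oracle_anbc(a))
            assert average_edge_betweenness(c) == pytest.approx(oracles.oracle_aebc(a))
            ar, ar_oracle = average_radiality(c), oracles.oracle_ar(a)
            if ar_oracle is None:
                assert ar is None
            else:
                assert ar == pytest.approx(ar_oracle)
            cn, lcl = cn_lcl_arrays(c)
            assert sorted(zip(cn, lcl)) == sorted(oracles.oracle_cn_lcl(a).values())


class TestNullNetworks:
    def test_random_equivalent_preserves_degree_sequence(self):
        c = connected_er(30, 90, 1)
        r = random_equivalent(c, NullEnsembleConfig(1, 10, 4))
        np.testing.assert_array_equal(
            np.sort(r.adjacency.sum(1)), np.sort(c.adjacency.sum(1))
        )

    def test_random_equivalent_preserves_connectedness(self):
        ring = from_nx(nx.watts_strogatz_graph(40, 4, 0.0, seed=0))
        for s in range(5):
            r = random_equivalent(ring, NullEnsembleConfig(1, 10, s))
            assert nx.is_connected(r.to_networkx())

    def test_k4_returned_unchanged_with_warning(self, k4):
        with pytest.warns(UserWarning, match="no admissible"):
            r = random_equivalent(k4, NullEnsembleConfig(1, 10, 0))
        np.testing.assert_array_equal(r.adjacency, k4.adjacency)

    def test_randomizing_a_ring_shortens_paths(self):
        ring = from_nx(nx.watts_strogatz_graph(50, 4, 0.0, seed=0))
        cpl0 = characteristic_path_length(ring)
        for s in range(10):
            r = random_equivalent(ring, NullEnsembleConfig(1, 10, s))
            assert characteristic_path_length(r) < cpl0

    def test_latticization_preserves_degrees_and_raises_clustering(self):
        wins = 0
        for s in range(10):
            g = nx.gnp_random_graph(50, 0.15, seed=s)
            c = from_nx(g)
            lat = lattice_equivalent(c, NullEnsembleConfig(1, 10, s))
            np.testing.assert_array_equal(
                np.sort(lat.adjacency.sum(1)), np.sort(c.adjacency.sum(1))
            )
            wins += average_clustering_coefficient(lat) >= average_clustering_coefficient(c)
        assert wins >= 9

    def test_ring_lattice_is_already_latticized(self):
        ring = from_nx(nx.watts_strogatz_graph(50, 4, 0.0, seed=1))
        lat = lattice_equivalent(ring, NullEnsembleConfig(1, 10, 7))
        acc0 = average_clustering_coefficient(ring)
        assert abs(average_clustering_coefficient(lat) - acc0) <= 0.05 * acc0


class TestSmallWorldness:
    def test_sigma_near_one_on_er(self):
        vals = [
            smallworldness_sigma(connected_er(100, 400, s), NullEnsembleConfig(10, 10, s))
            for s in range(10)
        ]
        assert abs(np.mean(vals) - 1) < 0.3

    def test_sigma_above_one_on_watts_strogatz(self):
        ws = from_nx(nx.watts_strogatz_graph(100, 6, 0.1, seed=2))
        assert smallworldness_sigma(ws, NullEnsembleConfig(10, 10, 3)) > 1

    def test_sigma_seeded_determinism(self):
        c = connected_er(60, 240, 9)
        cfg = NullEnsembleConfig(3, 10, 5)
        assert smallworldness_sigma(c, cfg) == smallworldness_sigma(c, cfg)

    def test_omega_negative_on_ring_lattice(self):
        ring = from_nx(nx.watts_strogatz_graph(100, 4, 0.0, seed=1))
        assert smallworldness_omega(ring, NullEnsembleConfig(10, 10, 1)) < 0

    def test_omega_positive_on_er(self):
        assert smallworldness_omega(connected_er(100, 400, 3), NullEnsembleConfig(10, 10, 2)) > 0

    def test_omega_near_zero_on_small_world(self):
        ws = from_nx(nx.watts_strogatz_graph(100, 6, 0.05, seed=2))
        assert abs(smallworldness_omega(ws, NullEnsembleConfig(10, 10, 4))) < 0.5


class TestPowerLawness:
    def test_well_specified_null_is_accepted(self):
        accepted = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            vals = _sample_discrete_pl(rng, 2.5, 1, 1000)
            accepted += power_law_pvalue(vals, n_bootstrap=100, seed=s + 100) >= 0.1
        assert accepted >= 8

    def test_p_in_unit_interval_and_deterministic(self):
        c = connected_er(40, 100, 2)
        p1 = power_lawness(c, n_bootstrap=50, seed=3)
        p2 = power_lawness(c, n_bootstrap=50, seed=3)
        assert p1 == p2 and 0 <= p1 <= 1

    def test_degenerate_degree_sequence_undefined(self, k4):
        assert power_lawness(k4, n_bootstrap=10, seed=0) is None


class TestModularity:
    def test_two_disjoint_triangles(self, two_triangles):
        assert modularity(two_triangles, seed=1) == pytest.approx(0.5)
        assert oracles.oracle_modularity_opt(two_triangles.adjacency) == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        k6 = make_connectome([(i, j) for i in range(6) for j in range(i + 1, 6)], 6)
        assert modularity_of_partition(k6, [set(range(6))]) == pytest.approx(0.0)
        assert modularity(k6, seed=1) >= 0

    def test_matches_exhaustive_oracle_on_small_graphs(self):
        for a in oracles.connected_atlas_graphs(max_n=5):
            ids = [f"n{k}" for k in range(a.shape[0])]
            c = Connectome(a, ids, {v: "S1" for v in ids}, binary=True)
            opt = oracles.oracle_modularity_opt(a)
            assert modularity(c, seed=2) == pytest.approx(opt, abs=1e-9)
            # the large-graph heuristic path never exceeds the optimum
            assert modularity(c, seed=2, exact_threshold=0) <= opt + 1e-9

    def test_matches_oracle_on_random_n8_graphs(self):
        for s in range(5):
            g = nx.gnp_random_graph(8, 0.35, seed=s)
            if g.number_of_edges() == 0:
                continue
            c = from_nx(g)
            opt = oracles.oracle_modularity_opt(c.adjacency)
            assert modularity(c, seed=3) == pytest.approx(opt, abs=1e-9)
            assert modularity(c, seed=3, exact_threshold=0) <= opt + 1e-9

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            modularity(make_connectome([], 3), seed=0)


class TestStructuralConsistency:
    def test_bounded_and_deterministic(self):
        c = connected_er(50, 250, 4)
        v1 = structural_consistency(c, 0.1, 5, seed=8)
        v2 = structural_consistency(c, 0.1, 5, seed=8)
        assert v1 == v2 and 0 <= v1 <= 1

    def test_stability_over_repeats(self):
        c = connected_er(50, 250, 6)
        mean, se = stability_check(
            lambda cc, s: structural_consistency(cc, 0.1, 1, seed=s), c, k=20, seed=1
        )
        assert se < 0.05

    def test_too_few_edges_raises(self, path3):
        with pytest.raises(ValueError):
            structural_consistency(path3, 0.1, 2, seed=0)


class TestMeasureAll:
    def test_exactly_fourteen_named_values(self, f6):
        gm = measure_all(f6, MeasureConfig(n_bootstrap=20, sc_repeats=2))
        assert len(gm.as_dict()) == 14

    def test_k3_values(self, k3):
        gm = measure_all(k3, MeasureConfig(n_bootstrap=10, sc_repeats=2))
        assert gm.AND == 2 and gm.CPL == 1 and gm.AE == 1 and gm.ACC == 1
        assert gm.ANBC == 0
        assert gm.AR is None

    def test_seeded_bit_identical(self):
        c = connected_er(20, 60, 5)
        cfg = MeasureConfig(n_bootstrap=20, sc_repeats=2, seed=9)
        assert measure_all(c, cfg) == measure_all(c, cfg)

    def test_csv_row_has_empty_cells_for_undefined(self, k3):
        gm = measure_all(k3, MeasureConfig(n_bootstrap=10, sc_repeats=2))
        row = gm.to_csv_row().split(",")
        assert len(row) == 14
        assert row[7] == ""  # radiality undefined on K3


class TestStabilityCheck:
    def test_deterministic_measure_has_zero_se(self, f6):
        mean, se = stability_check(lambda c, s: average_node_degree(c), f6, k=5, seed=0)
        assert se == 0.0
        assert mean == average_node_degree(f6)

    def test_mean_equals_arithmetic_mean_of_draws(self):
        c = connected_er(30, 120, 2)
        draws = {}

        def fn(cc, s):
            v = structural_consistency(cc, 0.1, 1, seed=s)
            draws[s] = v
            return v

        mean, se = stability_check(fn, c, k=6, seed=3)
        assert mean == pytest.approx(np.mean(list(draws.values())))
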