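import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.linalg import expm
from statsmodels.stats.multitest import multipletests

from phyconiche.network import (
    attack_robustness,
    compare_slopes,
    detect_modules,
    exact_spearman_pvalue,
    induced_subgraph,
    natural_connectivity,
    spearman_edges,
    topology,
)
from phyconiche.synthetic import generate_community


def brute_force_spearman_p(x, y):
    """Oracle: enumerate every permutation of y, count |rho| >= |rho_obs|."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


class TestSpearmanEdges:
    def _rel(self, rows, ids=None):
        ids = ids or [f"o{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids)

    def test_perfectly_monotone_profiles_connected_with_rho_one(self):
        rel = self._rel([[1, 2, 3, 4, 5, 6, 7, 8],
                         [2, 4, 8, 9, 12, 20, 21, 30],
                         [8, 7, 6, 5, 4, 3, 2, 1]])
        g = spearman_edges(rel, r_min=0.6, alpha=0.05)
        assert g.edges["o0", "o1"]["r"] == pytest.approx(1.0)
        assert g.edges["o0", "o2"]["r"] == pytest.approx(-1.0)
        assert g.edges["o0", "o2"]["sign"] == -1

    def test_exact_p_matches_brute_force_small_n(self):
        rng = np.random.default_rng(0)
        for n in (5, 6):
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, p = exact_spearman_pvalue(x, y)
            assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_matches_brute_force(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 2.0, 5.0, 5.0])
        _, p = exact_spearman_pvalue(x, y)
        assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_benjamini_hochberg_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(size=40)
        adj = multipletests(raw, method="fdr_bh")[1]
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_constant_otu_excluded(self):
        rel = self._rel([[1, 1, 1, 1, 1, 1, 1, 1],
                         [1, 2, 3, 4, 5, 6, 7, 8],
                         [2, 3, 4, 5, 6, 7, 8, 9]])
        g = spearman_edges(rel, keep_isolated=True)
        assert "o0" not in g.nodes

    def test_edges_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        rel = self._rel(rng.uniform(size=(10, 8)))
        g1 = spearman_edges(rel, r_min=0.4)
        g2 = spearman_edges(rel.iloc[::-1], r_min=0.4)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


class TestSubgraphsAndTopology:
    def _attributed_graph(self):
        g = nx.Graph()
        for n, cls in [("a", "generalist"), ("b", "generalist"),
                       ("c", "specialist"), ("d", "specialist")]:
            g.add_node(n, niche_class=cls)
        for u, v in [("a", "b"), ("c", "d"), ("a", "c"), ("b", "d")]:
            g.add_edge(u, v, r=0.8, p_adj=0.01, sign=1, weight=0.8)
        return g

    def test_filter_matching_all_nodes_is_identity(self):
        g = self._attributed_graph()
        sub = induced_subgraph(g)
        assert set(sub.nodes) == set(g.nodes) and sub.number_of_edges() == 4

    def test_triangle_with_one_node_removed_keeps_single_edge(self):
        g = nx.Graph()
        g.add_node("x", niche_class="generalist")
        g.add_node("y", niche_class="generalist")
        g.add_node("z", niche_class="specialist")
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")], sign=1, weight=1.0)
        sub = induced_subgraph(g, niche_class="generalist")
        assert sub.number_of_edges() == 1

    def test_partition_edge_counts_sum_to_total(self):
        g = self._attributed_graph()
        e_gen = induced_subgraph(g, niche_class="generalist").number_of_edges()
        e_spec = induced_subgraph(g, niche_class="specialist").number_of_edges()
        cross = sum(
            1 for u, v in g.edges
            if g.nodes[u]["niche_class"] != g.nodes[v]["niche_class"]
        )
        assert e_gen + e_spec + cross == g.number_of_edges()

    def test_triangle_topology_hand_computed(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        nx.set_edge_attributes(g, 1, "sign")
        stats = topology(g)
        assert stats["nodes"] == 3 and stats["edges"] == 3
        assert stats["avg_degree"] == pytest.approx(2.0)
        assert stats["complexity"] == pytest.approx(1.0)
        assert stats["positive_edge_fraction"] == 1.0

    def test_two_cliques_modularity_hand_formula(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        stats = topology(g)
        # two blocks, no cross edges: Q = sum(e_ii - a_i^2) = 1 - 2*(1/2)^2
        assert stats["modularity"] == pytest.approx(0.5)

    def test_modules_match_components_and_are_stable(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        nx.set_edge_attributes(g, 1.0, "weight")
        m1 = detect_modules(g, seed=0)
        m2 = detect_modules(g, seed=0)
        assert m1 == m2
        assert len(set(m1.values())) == 2
        comps = list(nx.connected_components(g))
        for comp in comps:
            assert len({m1[n] for n in comp}) == 1


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        g = nx.empty_graph(6)
        assert natural_connectivity(g) == pytest.approx(0.0)

    def test_complete_graph_closed_form(self):
        g = nx.complete_graph(4)
        expected = math.log((math.exp(3) + 3 * math.exp(-1)) / 4)
        assert natural_connectivity(g) == pytest.approx(expected, abs=1e-12)

    def test_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = nx.gnp_random_graph(rng.integers(2, 12), 0.4, seed=int(rng.integers(1e9)))
            a = nx.to_numpy_array(g)
            oracle = math.log(np.trace(expm(a)) / a.shape[0])
            assert natural_connectivity(g) == pytest.approx(oracle, abs=1e-10)


class TestAttackRobustness:
    def _graph(self, n=30, p=0.2, seed=0):
        g = nx.gnp_random_graph(n, p, seed=seed)
        return g

    def test_zero_proportion_equals_intact_connectivity(self):
        g = self._graph()
        curve = attack_robustness(g, proportions=[0.0, 0.3], n_reps=5, seed=0)
        assert curve.mean_connectivity[0] == pytest.approx(natural_connectivity(g))

    def test_curve_nonincreasing_within_noise(self):
        g = self._graph(40, 0.25, seed=1)
        curve = attack_robustness(
            g, proportions=np.arange(0, 0.81, 0.1), n_reps=60, seed=2
        )
        se = curve.sd_connectivity / np.sqrt(curve.n_reps)
        diffs = np.diff(curve.mean_connectivity)
        tol = 2 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
        assert (diffs <= tol + 1e-9).all()

    def test_denser_graph_dominates_sparse_under_attack(self):
        # at equal N the denser graph keeps strictly higher natural
        # connectivity at every removal proportion (robustness dominance)
        wins = 0
        for seed in range(20):
            sparse = nx.gnp_random_graph(30, 0.12, seed=100 + seed)
            dense = nx.gnp_random_graph(30, 0.5, seed=200 + seed)
            props = np.arange(0, 0.81, 0.1)
            cs = attack_robustness(sparse, proportions=props, n_reps=20, seed=seed)
            cd = attack_robustness(dense, proportions=props, n_reps=20, seed=seed)
            wins += (cd.mean_connectivity > cs.mean_connectivity).all()
        assert wins >= 18

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            attack_robustness(self._graph(), proportions=[0.0, 1.0], n_reps=2)

    def test_tiny_graph_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            attack_robustness(nx.path_graph(3))


class TestCompareSlopes:
    def _curve(self, slope, seed):
        g = nx.gnp_random_graph(30, 0.3, seed=seed)
        curve = attack_robustness(g, proportions=np.arange(0, 0.81, 0.1),
                                  n_reps=10, seed=seed)
        rng = np.random.default_rng(seed)
        curve.mean_connectivity = (
            5.0 + slope * curve.proportions + rng.normal(0, 0.02, curve.proportions.size)
        )
        return curve

    def test_curve_against_itself_zero_difference(self):
        c = self._curve(-1.0, 0)
        diff, _, p = compare_slopes(c, c)
        assert diff == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_constructed_slope_difference_detected(self):
        a = self._curve(-1.0, 1)
        b = self._curve(-2.0, 2)
        diff, t, p = compare_slopes(a, b)
        assert diff == pytest.approx(1.0, abs=0.2)
        assert p < 0.01
        # sign convention: b is steeper (more negative), so a - b > 0
        assert diff > 0

    def test_mismatched_grids_rejected(self):
        a = self._curve(-1.0, 1)
        b = self._curve(-1.0, 2)
        b.proportions = b.proportions + 0.01
        with pytest.raises(ValueError, match="grids"):
            compare_slopes(a, b)


class TestWholeCommunityNetwork:
    def test_build_from_synthetic_community(self, community_scenario):
        from phyconiche.niche import classify

        table = community_scenario.otu_table
        profiles = classify(table, "bacteria")
        rel = table.relative_abundance()
        keep = profiles.index[profiles["niche_class"] != "filtered"]
        g = spearman_edges(
            rel.loc[keep], r_min=0.6, alpha=0.05,
            node_attrs=profiles[["niche_class"]],
        )
        assert g.number_of_edges() > 0
        for _, _, d in g.edges(data=True):
            assert abs(d["r"]) > 0.6 and d["p_adj"] < 0.05
        stats = topology(g)
        assert stats["edges"] >= sum(
            topology(induced_subgraph(g, niche_class=c))["edges"]
            for c in ("generalist", "specialist")
        )
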