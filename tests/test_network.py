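"""SparCC inference, network construction, roles, robustness, env edges."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pelagos.containers import OtuTable
from pelagos.network import (
    bh_adjust,
    build_network,
    complexity_diversity_regression,
    detect_modules_and_roles,
    env_edge_test,
    keystone_overlap,
    keystones,
    natural_connectivity,
    robustness_attack,
    sparcc,
    topology_summary,
)
from pelagos.synthetic import simulate_correlated_counts


class TestSparcc:
    def test_symmetric_unit_diagonal(self):
        tbl, _ = simulate_correlated_counts(40, 10, [], seed=0)
        r, p = sparcc(tbl, n_bootstrap=10, seed=1)
        m = r.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert ((m >= -1) & (m <= 1)).all()

    def test_duplicated_otu_near_one(self):
        tbl, _ = simulate_correlated_counts(50, 8, [], seed=2)
        first = tbl.otu_ids[0]
        counts = tbl.counts.copy()
        counts["dup"] = counts[first]
        r, _ = sparcc(OtuTable(counts), n_bootstrap=5, seed=3)
        assert r.loc[first, "dup"] > 0.9

    def test_sample_order_invariance(self):
        tbl, _ = simulate_correlated_counts(30, 8, [(0, 1, 0.8)], seed=4)
        r1, _ = sparcc(tbl, n_iterations=5, n_bootstrap=0, seed=5)
        shuffled = OtuTable(tbl.counts.iloc[::-1])
        r2, _ = sparcc(shuffled, n_iterations=5, n_bootstrap=0, seed=5)
        # same seed, same Dirichlet stream applied to different rows: values
        # differ by resampling noise only
        a, b = tbl.otu_ids[0], tbl.otu_ids[1]
        assert abs(r1.loc[a, b] - r2.loc[a, b]) < 0.1

    def test_too_few_otus_rejected(self):
        tbl, _ = simulate_correlated_counts(20, 3, [], seed=6)
        with pytest.raises(ValueError, match="at least 4"):
            sparcc(tbl)


class TestBhAdjustment:
    def test_matches_brute_force_definition(self, rng):
        """BH step-up: p_adj(i) = min over j>=i of p(j)*n/j (sorted)."""
        for _ in range(50):
            p = rng.random(20)
            mine = bh_adjust(p)
            order = np.argsort(p)
            n = len(p)
            sorted_adj = p[order] * n / np.arange(1, n + 1)
            stepped = np.minimum.accumulate(sorted_adj[::-1])[::-1]
            brute = np.empty(n)
            brute[order] = np.minimum(stepped, 1.0)
            assert np.allclose(mine, brute, rtol=0, atol=1e-12)


class TestBuildNetwork:
    def _mats(self, r_vals, p_vals, ids):
        n = len(ids)
        r = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        p = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
        for (i, j), v in r_vals.items():
            r.iloc[i, j] = r.iloc[j, i] = v
        for (i, j), v in p_vals.items():
            p.iloc[i, j] = p.iloc[j, i] = v
        return r, p

    def test_strong_significant_edge_kept(self):
        ids = list("abcde")
        r, p = self._mats({(0, 1): 0.7}, {(0, 1): 0.0005}, ids)
        # make all other pairs non-significant
        p[:] = 0.9
        p.iloc[0, 1] = p.iloc[1, 0] = 0.0005
        g = build_network(r, p)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["sign"] == "positive"

    def test_below_rmin_rejected_despite_significance(self):
        ids = list("abcde")
        r, p = self._mats({(0, 1): 0.59}, {}, ids)
        p[:] = 0.9
        p.iloc[0, 1] = p.iloc[1, 0] = 0.0001
        with pytest.warns(UserWarning, match="no edges"):
            g = build_network(r, p)
        assert g.number_of_edges() == 0

    def test_hand_bh_enumeration(self):
        """5x5 toy: edge set after BH matches hand-computed adjustment."""
        ids = list("abcde")
        r, p = self._mats(
            {(0, 1): 0.9, (0, 2): -0.8, (1, 2): 0.7, (3, 4): 0.65},
            {}, ids)
        p[:] = 1.0
        np.fill_diagonal(p.values, 0.0)
        raw = {(0, 1): 0.001, (0, 2): 0.002, (1, 2): 0.004, (3, 4): 0.05}
        for (i, j), v in raw.items():
            p.iloc[i, j] = p.iloc[j, i] = v
        # upper triangle has 10 p's: [0.001, 0.002, 0.004, 0.05, 1*6]
        # BH: 0.001*10/1=0.01 not < 0.01 -> all of the first three get
        # min over j>=i: 0.004*10/3=0.0133, 0.002*10/2=0.01, 0.001*10/1=0.01
        # so none pass alpha=0.01 strictly
        with pytest.warns(UserWarning, match="no edges"):
            g = build_network(r, p, alpha=0.01)
        assert g.number_of_edges() == 0
        g2 = build_network(r, p, alpha=0.02)
        assert set(map(frozenset, g2.edges)) == {
            frozenset("ab"), frozenset("ac"), frozenset("bc")}
        assert g2.edges["a", "c"]["sign"] == "negative"

    def test_isolated_nodes_dropped(self):
        ids = list("abcd")
        r, p = self._mats({(0, 1): 0.9}, {}, ids)
        p[:] = 0.9
        p.iloc[0, 1] = p.iloc[1, 0] = 0.0001
        g = build_network(r, p)
        assert set(g.nodes) == {"a", "b"}


class TestTopology:
    def test_complete_graph_closed_form(self):
        topo = topology_summary(nx.complete_graph(4), n_random=2)
        assert topo["density"] == pytest.approx(1.0)
        assert topo["average_clustering_coefficient"] == pytest.approx(1.0)
        assert topo["average_path_length"] == pytest.approx(1.0)

    def test_path_graph_hand_values(self):
        topo = topology_summary(nx.path_graph(3), n_random=2)
        assert topo["average_degree"] == pytest.approx(4 / 3)
        assert topo["average_clustering_coefficient"] == pytest.approx(0.0)

    def test_powerlaw_fixture_good_fit(self):
        # construct an exact power-law degree histogram: freq(k) ~ k^-2
        degrees = []
        for k in range(1, 9):
            degrees.extend([k] * int(round(1000 * k ** -2.0)))
        from pelagos.network import _powerlaw_fit
        exponent, r2 = _powerlaw_fit(degrees)
        assert r2 > 0.95
        assert exponent == pytest.approx(2.0, abs=0.3)


class TestRoles:
    def test_all_links_inside_module_p_zero(self):
        g = nx.barbell_graph(5, 0)
        roles = detect_modules_and_roles(g)
        inner = roles.drop(index=[4, 5])  # non-bridge nodes
        assert (inner["p"] == 0.0).all()

    def test_even_split_p_half(self):
        # node 'x' with 2 links, one into each of two 3-cliques
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                          ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                          ("x", "a1"), ("x", "b1")])
        roles = detect_modules_and_roles(g)
        assert roles.loc["x", "p"] == pytest.approx(0.5)

    def test_brute_force_recomputation(self):
        """z and p match direct recomputation from the partition."""
        g = nx.barbell_graph(6, 1)
        roles = detect_modules_and_roles(g)
        module_of = roles["module"].to_dict()
        for node in g.nodes:
            k = g.degree(node)
            kic: dict = {}
            for nb in g.neighbors(node):
                kic[module_of[nb]] = kic.get(module_of[nb], 0) + 1
            p_ref = 1 - sum((c / k) ** 2 for c in kic.values())
            assert roles.loc[node, "p"] == pytest.approx(p_ref, abs=1e-12)
            members = [n for n, m in module_of.items() if m == module_of[node]]
            vals = np.array([
                sum(1 for nb in g.neighbors(n) if module_of[nb] == module_of[n])
                for n in members], dtype=float)
            sd = vals.std()
            kib = sum(1 for nb in g.neighbors(node)
                      if module_of[nb] == module_of[node])
            z_ref = (kib - vals.mean()) / sd if sd > 0 else 0.0
            assert roles.loc[node, "z"] == pytest.approx(z_ref, abs=1e-12)

    def test_role_thresholds(self):
        # hub-and-spoke inside one module -> high z, p = 0
        g = nx.star_graph(14)
        g.add_edges_from([(i, i + 1) for i in range(1, 13)])
        roles = detect_modules_and_roles(g)
        # the centre has far more within-module links than the leaves
        assert roles.loc[0, "z"] > roles.drop(index=0)["z"].max()

    def test_keystone_overlap_hand_cases(self):
        def _roles(names, role="connector"):
            return pd.DataFrame({"role": [role] * len(names)}, index=names)
        a = _roles(["x", "y", "z"])
        b = _roles(["x", "u", "v"])
        res = keystone_overlap(a, b)
        assert res["shared"] == ["x"]
        assert res["shared_fraction"] == pytest.approx(1 / 5)
        same = keystone_overlap(a, a)
        assert same["shared_fraction"] == pytest.approx(1.0)
        disjoint = keystone_overlap(_roles(["q"]), _roles(["w"]))
        assert disjoint["shared_fraction"] == pytest.approx(0.0)

    def test_peripherals_are_not_keystones(self):
        df = pd.DataFrame({"role": ["peripheral", "connector", "module_hub",
                                    "network_hub"]},
                          index=["a", "b", "c", "d"])
        assert keystones(df) == {"b", "c", "d"}


class TestNaturalConnectivity:
    def test_empty_graph_zero(self):
        assert natural_connectivity(nx.empty_graph(7)) == pytest.approx(0.0)

    def test_k3_closed_form(self):
        expected = np.log((np.e ** 2 + 2 * np.e ** -1) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 5, 10, 25, 50])
    def test_complete_graph_closed_form(self, n):
        expected = np.log((np.exp(n - 1) + (n - 1) * np.exp(-1.0)) / n)
        assert natural_connectivity(nx.complete_graph(n)) == pytest.approx(
            expected, abs=1e-9)

    def test_nondecreasing_under_edge_addition(self, rng):
        g = nx.gnm_random_graph(10, 12, seed=3)
        base = natural_connectivity(g)
        non_edges = list(nx.non_edges(g))
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        g.add_edge(u, v)
        assert natural_connectivity(g) >= base - 1e-12


class TestRobustness:
    def test_complete_graph_strategy_independent(self):
        g = nx.complete_graph(6)
        c1 = robustness_attack(g, "betweenness").connectivity
        c2 = robustness_attack(g, "degree").connectivity
        c3 = robustness_attack(g, "random", n_reps=3, seed=0).connectivity
        assert np.allclose(c1, c2)
        assert np.allclose(c1, c3)  # vertex-transitive: any order identical

    def test_star_hub_removal_collapses(self):
        g = nx.star_graph(6)
        targeted = robustness_attack(g, "degree").connectivity
        assert targeted[0] > 0.5
        assert np.allclose(targeted[1:], 0.0, atol=1e-9)

    def test_random_matches_brute_force_on_five_nodes(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)])
        nodes = sorted(g.nodes)

        def brute_curve(order):
            vals = [natural_connectivity(g)]
            h = g.copy()
            for v in order:
                h.remove_node(v)
                if h.number_of_nodes() < 2:
                    break
                vals.append(natural_connectivity(
                    nx.to_numpy_array(h, nodelist=sorted(h.nodes))))
            return np.array(vals)

        exact = np.mean([brute_curve(o)
                         for o in itertools.permutations(nodes)], axis=0)
        mc = robustness_attack(g, "random", n_reps=3000, seed=7).connectivity
        assert np.allclose(mc, exact, atol=0.02)

    def test_random_requires_n_reps(self):
        with pytest.raises(ValueError, match="n_reps"):
            robustness_attack(nx.complete_graph(4), "random")

    def test_seed_determinism(self):
        g = nx.gnm_random_graph(8, 12, seed=1)
        a = robustness_attack(g, "random", n_reps=10, seed=5).connectivity
        b = robustness_attack(g, "random", n_reps=10, seed=5).connectivity
        assert np.array_equal(a, b)


class TestEnvEdges:
    def _network_and_table(self, rng, env_driven):
        n = 40
        temp = np.linspace(20, 5, n)
        counts = np.zeros((n, 6), dtype=int)
        if env_driven:
            a = np.exp(0.2 * temp)
            b = np.exp(0.21 * temp)
        else:
            z = rng.normal(size=n)
            a = np.exp(1.5 * z)
            b = np.exp(1.4 * z + 0.1 * rng.normal(size=n))
        counts[:, 0] = np.round(500 * a / a.max()) + 1
        counts[:, 1] = np.round(500 * b / b.max()) + 1
        counts[:, 2:] = rng.integers(1, 50, size=(n, 4))
        tbl = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n)],
            columns=[f"o{j}" for j in range(6)]))
        g = nx.Graph()
        g.add_edge("o0", "o1", r=0.9, sign="positive")
        env = pd.DataFrame({"temperature": temp}, index=tbl.sample_ids)
        return g, tbl, env

    def test_env_driven_edge_labelled(self, rng):
        g, tbl, env = self._network_and_table(rng, env_driven=True)
        edges, summary = env_edge_test(g, tbl, env)
        assert summary["n_env_edges"] == 1
        assert edges.iloc[0]["label"] == "taxon-taxon-environment"

    def test_env_independent_edge_stays_taxon_taxon(self, rng):
        g, tbl, env = self._network_and_table(rng, env_driven=False)
        edges, summary = env_edge_test(g, tbl, env)
        assert summary["n_env_edges"] == 0
        assert edges.iloc[0]["label"] == "taxon-taxon"

    def test_empty_env_all_taxon_taxon(self, rng):
        g, tbl, _ = self._network_and_table(rng, env_driven=True)
        edges, summary = env_edge_test(g, tbl,
                                       pd.DataFrame(index=tbl.sample_ids))
        assert summary["n_env_edges"] == 0

    def test_constant_variable_skipped(self, rng):
        g, tbl, env = self._network_and_table(rng, env_driven=True)
        env["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            _, summary = env_edge_test(g, tbl, env)
        assert "flat" not in summary["per_variable"]


class TestComplexityRegression:
    def test_sample_with_all_otus_counts_full_network(self, rng):
        tbl, _ = simulate_correlated_counts(10, 6, [], seed=8,
                                            n_reads_per_sample=500)
        g = nx.Graph()
        g.add_edges_from([("o0001", "o0002"), ("o0002", "o0003")])
        # ensure the first sample holds every network OTU
        counts = tbl.counts.copy()
        counts.iloc[0] += 1
        tbl = OtuTable(counts)
        alpha = pd.DataFrame(
            {"richness": (tbl.counts > 0).sum(axis=1)}, index=tbl.sample_ids)
        reg = complexity_diversity_regression(g, tbl, alpha)
        assert set(reg["response"]) == {"nodes", "edges"}

    def test_nested_structure_positive_slope(self):
        # nested presence: each richer sample is a superset
        n_otus = 8
        counts = np.zeros((8, n_otus), dtype=int)
        for i in range(8):
            counts[i, : i + 1] = 10
        tbl = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(8)],
            columns=[f"o{j}" for j in range(n_otus)]))
        g = nx.Graph()
        g.add_edges_from([(f"o{j}", f"o{j+1}") for j in range(n_otus - 1)])
        alpha = pd.DataFrame(
            {"richness": (tbl.counts > 0).sum(axis=1)}, index=tbl.sample_ids)
        reg = complexity_diversity_regression(g, tbl, alpha)
        assert (reg["slope"] > 0).all()
        assert (~reg["omitted"]).all()

    def test_shuffled_richness_flagged_omitted(self, rng):
        counts = rng.integers(0, 5, size=(12, 10))
        counts[:, 0] += 1
        tbl = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(12)],
            columns=[f"o{j}" for j in range(10)]))
        g = nx.Graph()
        g.add_edges_from([("o0", "o1"), ("o1", "o2")])
        fake = pd.DataFrame({"noise": rng.permutation(np.arange(12.0))},
                            index=tbl.sample_ids)
        reg = complexity_diversity_regression(g, tbl, fake)
        assert reg["r_squared"].max() < 0.5  # no systematic signal
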