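import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutkeystone import network, preprocess
from gutkeystone.simulate import SimulationConfig, simulate_cohorts
from conftest import hand_bh, power_iteration_centrality


def _net_from_matrix(a, taxa):
    a = np.asarray(a, dtype=float)
    return network.CoAbundanceNetwork(
        adjacency=pd.DataFrame(a, index=taxa, columns=taxa), method="test"
    )


class TestPearsonNetwork:
    def test_duplicated_taxon_perfect_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        clr = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        net = network.pearson_network(clr)
        assert net.adjacency.loc["a", "b"] > 0.999

    def test_independent_columns_empty(self):
        rng = np.random.default_rng(1)
        clr = pd.DataFrame(rng.normal(size=(500, 20)))
        net = network.pearson_network(clr)
        assert net.n_edges == 0

    def test_planted_block_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        n = 500
        f = rng.normal(size=n)
        cols = {f"t{j}": np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(size=n) for j in range(3)}
        cols.update({f"bg{j}": rng.normal(size=n) for j in range(10)})
        clr = pd.DataFrame(cols)
        net = network.pearson_network(clr)
        # independent oracle: scipy pearsonr per pair + hand-applied BH
        pairs = list(itertools.combinations(clr.columns, 2))
        rs, ps = zip(*(stats.pearsonr(clr[a], clr[b]) for a, b in pairs))
        padj = hand_bh(np.array(ps))
        expected = {
            frozenset((a, b))
            for (a, b), r, q in zip(pairs, rs, padj)
            if abs(r) > 0.3 and q < 0.05
        }
        got = {
            frozenset((row["taxon_a"], row["taxon_b"]))
            for _, row in net.edge_list().iterrows()
        }
        assert got == expected

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        clr = pd.DataFrame({"a": rng.normal(size=50), "flat": np.zeros(50)})
        with pytest.warns(UserWarning, match="constant"):
            net = network.pearson_network(clr)
        assert "flat" not in net.taxon_ids


class TestSparcc:
    def test_rho_symmetric_unit_diagonal(self, small_dataset):
        table = preprocess.filter_prevalence(small_dataset.counts["cohort1"])
        net = network.sparcc(table, n_bootstrap=10, seed=0)
        rho = net.extras["rho"].to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_shuffled_compositions_empty(self, small_dataset):
        rng = np.random.default_rng(4)
        table = preprocess.filter_prevalence(small_dataset.counts["cohort1"]).copy()
        for col in table.columns:  # break all dependence
            table[col] = rng.permutation(table[col].to_numpy())
        net = network.sparcc(table, n_bootstrap=50, seed=5)
        n_pairs = len(table.columns) * (len(table.columns) - 1) / 2
        assert net.n_edges / n_pairs < 0.005

    def test_planted_pair_recovered(self):
        # one strongly correlated pair among 50 background taxa
        rng = np.random.default_rng(6)
        n, p_bg = 300, 50
        f = rng.normal(size=n)
        z = np.column_stack(
            [
                1.0 + np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(size=n),
                1.0 + np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(size=n),
                rng.normal(0, 1, size=(n, p_bg)),
            ]
        )
        comp = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(30000, c) for c in comp])
        table = pd.DataFrame(counts, columns=[f"t{j}" for j in range(p_bg + 2)])
        net = network.sparcc(table, n_bootstrap=50, seed=7)
        assert net.extras["rho"].loc["t0", "t1"] > 0.5
        assert net.adjacency.loc["t0", "t1"] > 0


class TestSpiecEasi:
    def test_independent_taxa_near_empty(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, size=(300, 30))
        comp = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(20000, c) for c in comp])
        table = pd.DataFrame(counts, columns=[f"t{j}" for j in range(30)])
        net = network.spieceasi(table, n_subsamples=20, seed=9)
        n_pairs = 30 * 29 / 2
        assert net.n_edges / n_pairs < 0.02

    def test_planted_hub_neighbors_recovered(self):
        # hub driving 5 satellites through strong partial correlations, among
        # a realistic number of background taxa (the CLR closure artifact
        # scales as 1/p and would dominate in a tiny table)
        rng = np.random.default_rng(10)
        n = 400
        hub = rng.normal(size=n)
        sats = [0.75 * hub + np.sqrt(1 - 0.75**2) * rng.normal(size=n) for _ in range(5)]
        bg = rng.normal(0, 1, size=(n, 94))
        z = np.column_stack([hub] + sats + [bg])
        comp = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(30000, c) for c in comp])
        names = ["hub"] + [f"sat{j}" for j in range(5)] + [f"bg{j}" for j in range(94)]
        table = pd.DataFrame(counts, columns=names)
        net = network.spieceasi(table, n_subsamples=20, seed=11)
        neighbors = set(net.adjacency.columns[net.adjacency.loc["hub"] > 0])
        true_neighbors = {f"sat{j}" for j in range(5)}
        jaccard = len(neighbors & true_neighbors) / max(1, len(neighbors | true_neighbors))
        assert jaccard >= 0.6

    def test_deterministic_for_fixed_seed(self, small_dataset):
        table = preprocess.filter_prevalence(small_dataset.counts["cohort1"])
        a = network.spieceasi(table, n_subsamples=5, seed=12)
        b = network.spieceasi(table, n_subsamples=5, seed=12)
        pd.testing.assert_frame_equal(a.adjacency, b.adjacency)

    def test_glasso_variant_not_available(self, small_dataset):
        table = preprocess.filter_prevalence(small_dataset.counts["cohort1"])
        with pytest.raises(NotImplementedError):
            network.spieceasi(table, variant="glasso")


class TestModules:
    def test_two_cliques(self):
        g = np.zeros((8, 8))
        g[np.ix_(range(4), range(4))] = 1
        g[np.ix_(range(4, 8), range(4, 8))] = 1
        np.fill_diagonal(g, 0)
        net = _net_from_matrix(g, list("abcdefgh"))
        modules = network.detect_modules(net)
        assert modules.nunique() == 2
        assert modules["a"] == modules["d"] != modules["e"]

    def test_empty_graph_all_singletons(self):
        net = _net_from_matrix(np.zeros((4, 4)), list("abcd"))
        modules = network.detect_modules(net)
        assert modules.nunique() == 4

    def test_matches_bruteforce_bipartition_modularity(self):
        # two 5-cliques joined by one edge; compare against the best
        # bipartition found by exhaustive search over all 2^9 splits
        g = np.zeros((10, 10))
        g[np.ix_(range(5), range(5))] = 1
        g[np.ix_(range(5, 10), range(5, 10))] = 1
        g[4, 5] = g[5, 4] = 1
        np.fill_diagonal(g, 0)
        taxa = [f"n{i}" for i in range(10)]
        net = _net_from_matrix(g, taxa)
        graph = net.to_networkx()
        best_q, best_split = -1.0, None
        for bits in range(1, 2**9):  # node 0 fixed in part A; skip trivial split
            part_a = {taxa[0]} | {taxa[i + 1] for i in range(9) if bits >> i & 1}
            part_b = set(taxa) - part_a
            q = nx.community.modularity(graph, [part_a, part_b], weight="weight")
            if q > best_q:
                best_q, best_split = q, (part_a, part_b)
        modules = network.detect_modules(net)
        found = {frozenset(modules.index[modules == m]) for m in modules.unique()}
        assert found == {frozenset(best_split[0]), frozenset(best_split[1])}


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self):
        a = 1 - np.eye(5)
        net = _net_from_matrix(a, list("abcde"))
        cent = network.eigenvector_centrality(net)
        np.testing.assert_allclose(cent.to_numpy(), 1.0)

    def test_star_center_maximal(self):
        a = np.zeros((6, 6))
        a[0, 1:] = a[1:, 0] = 1
        net = _net_from_matrix(a, list("abcdef"))
        cent = network.eigenvector_centrality(net)
        assert cent["a"] == 1.0
        assert (cent.drop("a") < 1.0).all()

    def test_weighted_graph_matches_power_iteration(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0, 1, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        net = _net_from_matrix(a, list("abcde"))
        cent = network.eigenvector_centrality(net)
        oracle = power_iteration_centrality(a)
        np.testing.assert_allclose(cent.to_numpy(), oracle, atol=1e-8)

    def test_leading_eigenvalue_satisfies_eigen_equation(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        net = _net_from_matrix(a, list("abcdef"))
        cent = network.eigenvector_centrality(net).to_numpy()
        lam = net.leading_eigenvalue
        np.testing.assert_allclose(a @ cent, lam * cent, atol=1e-8)

    def test_disconnected_component_zeroed(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1  # 2-node component
        a[np.ix_([2, 3, 4], [2, 3, 4])] = 1  # triangle = largest component
        np.fill_diagonal(a, 0)
        net = _net_from_matrix(a, list("abcde"))
        cent = network.eigenvector_centrality(net)
        assert (cent[["a", "b"]] == 0).all()
        assert (cent[["c", "d", "e"]] > 0).all()


class TestKeystoneCalling:
    def test_hundred_distinct_values_five_keystones(self):
        taxa = [f"t{i}" for i in range(100)]
        net = _net_from_matrix(np.zeros((100, 100)), taxa)
        net.centrality = pd.Series(np.linspace(0.01, 1.0, 100), index=taxa)
        ks = network.call_keystones(net)
        assert len(ks) == 5
        assert ks == set(taxa[-5:])

    def test_all_equal_empty(self):
        taxa = list("abcd")
        net = _net_from_matrix(np.zeros((4, 4)), taxa)
        net.centrality = pd.Series(0.5, index=taxa)
        assert network.call_keystones(net) == set()

    def test_hand_ranked_quantile(self):
        values = np.array([0.1] * 10 + [0.2] * 5 + [0.5, 0.6, 0.7, 0.9, 1.0])
        taxa = [f"t{i}" for i in range(20)]
        net = _net_from_matrix(np.zeros((20, 20)), taxa)
        net.centrality = pd.Series(values, index=taxa)
        cut = np.quantile(values, 0.95)  # linear interpolation convention
        expected = {t for t, v in zip(taxa, values) if v > cut}
        assert network.call_keystones(net) == expected


class TestSetCombination:
    def test_majority_rule(self):
        sets = {"m1": {"a", "b"}, "m2": {"b", "c"}, "m3": {"b"}}
        assert network.combine_methods(sets, "majority") == {"b"}

    def test_any_is_union_all_is_intersection(self):
        sets = {"m1": {"a"}, "m2": {"b"}, "m3": {"c"}}
        assert network.combine_methods(sets, "any") == {"a", "b", "c"}
        assert network.combine_methods(sets, "all") == set()

    def test_identical_sets_any_rule(self):
        sets = {"m1": {"x", "y"}, "m2": {"x", "y"}, "m3": {"x", "y"}}
        for rule in ("any", "majority", "all"):
            assert network.combine_methods(sets, rule) == {"x", "y"}

    def test_shared_keystones_intersection(self):
        cohorts = [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "b"}]
        assert network.shared_keystones(cohorts) == {"b", "c"}

    def test_shared_empty_cohort_gives_empty(self):
        with pytest.warns(UserWarning, match="no shared"):
            assert network.shared_keystones([{"a"}, set()]) == set()

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            network.combine_methods({"m": {"a"}}, "median")


class TestKeystoneIndex:
    def test_single_keystone_equals_clr_value(self):
        table = pd.DataFrame([[0, 9, 3]], columns=list("abc"))
        idx = network.keystone_index(table, {"a"})
        # counts+1 = (1,10,4): geometric mean 40^(1/3)
        expected = np.log(1) - np.log(40) / 3
        np.testing.assert_allclose(idx["index"].iloc[0], expected, atol=1e-12)

    def test_monotone_in_keystone_count(self):
        lo = pd.DataFrame([[5, 10, 10]], columns=list("abc"))
        hi = pd.DataFrame([[20, 10, 10]], columns=list("abc"))
        i_lo = network.keystone_index(lo, {"a"})["index"].iloc[0]
        i_hi = network.keystone_index(hi, {"a"})["index"].iloc[0]
        assert i_hi > i_lo

    def test_empty_set_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="empty"):
            network.keystone_index(toy_counts, set())

    def test_absent_keystone_contributes_pseudocount(self, toy_counts):
        idx = network.keystone_index(toy_counts, {"a", "not_in_table"})
        assert idx["index"].notna().all()

    def test_zscore_within_cohort(self, small_dataset):
        table = small_dataset.counts["cohort1"]
        cohorts = pd.Series("cohort1", index=table.index)
        idx = network.keystone_index(table, set(table.columns[:3]), cohorts=cohorts)
        assert abs(idx["index_z"].mean()) < 1e-9
        np.testing.assert_allclose(idx["index_z"].std(ddof=1), 1.0)


class TestRankRichnessCorrelates:
    def test_identical_to_richness_rank_one(self):
        rng = np.random.default_rng(15)
        richness = pd.Series(rng.integers(10, 60, 30).astype(float))
        abund = pd.DataFrame(
            {"match": richness.to_numpy(), "noise": rng.normal(size=30)}
        )
        out = network.rank_richness_correlates(abund, richness)
        top = out.iloc[0]
        assert top["taxon"] == "match"
        np.testing.assert_allclose(top["spearman_r"], 1.0)
        assert top["rank"] == 1

    def test_independent_genus_nonsignificant(self):
        rng = np.random.default_rng(16)
        richness = pd.Series(rng.integers(10, 60, 200).astype(float))
        abund = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"g{i}" for i in range(5)])
        out = network.rank_richness_correlates(abund, richness)
        assert (~out["significant"]).all()

    def test_matches_scipy_spearman_oracle(self):
        rng = np.random.default_rng(17)
        richness = pd.Series(rng.integers(5, 50, 12).astype(float))
        abund = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("wxyz"))
        out = network.rank_richness_correlates(abund, richness).set_index("taxon")
        for col in abund.columns:
            r_ref = stats.spearmanr(abund[col], richness).statistic
            np.testing.assert_allclose(out.loc[col, "spearman_r"], r_ref, atol=1e-12)
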