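import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from morelnet import network


def _abund(rows, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])], columns=samples)


class TestSpearman:
    def test_monotone_pair(self):
        a = _abund([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]])
        cm = network.spearman_matrix(a)
        assert cm.rho.iloc[0, 1] == pytest.approx(1.0)

    def test_anti_monotone_pair(self):
        a = _abund([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [20, 18, 16, 14, 12, 10, 8, 6, 4, 2]])
        cm = network.spearman_matrix(a)
        assert cm.rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson(self):
        x = [1, 2, 2, 3, 5, 5, 6, 7, 8, 8]
        y = [1, 3, 2, 4, 4, 6, 5, 8, 7, 9]
        a = _abund([x, y])
        cm = network.spearman_matrix(a)
        # oracle: rank with average ties, then plain Pearson
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert cm.rho.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(0)
        a = _abund(rng.random((6, 20)))
        cm = network.spearman_matrix(a)
        rho_ref, p_ref = stats.spearmanr(a.to_numpy().T)
        assert np.allclose(cm.rho.to_numpy(), rho_ref, atol=1e-10)
        iu = np.triu_indices(6, 1)
        assert np.allclose(cm.p.to_numpy()[iu], p_ref[iu], atol=1e-10)

    def test_constant_genus_flagged(self):
        a = _abund([[0.3] * 12, list(range(12))])
        cm = network.spearman_matrix(a)
        assert cm.constant_genera == ["g0"]
        assert cm.rho.iloc[0, 1] == 0.0
        assert cm.p.iloc[0, 1] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            network.spearman_matrix(_abund([[1, 2, 3], [3, 2, 1]]))

    def test_small_n_exact_permutation_p(self):
        # n = 6 < 10 samples -> exact enumeration of all 720 orderings
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        cm = network.spearman_matrix(_abund([x, y]))
        rho = stats.spearmanr(x, y).statistic
        # exact two-sided null: count orderings with |rho_perm| >= |rho|
        count = 0
        for perm in itertools.permutations(range(6)):
            r = stats.spearmanr(x, [y[i] for i in perm]).statistic
            count += abs(r) >= abs(rho) - 1e-12
        expected = (count + 1) / (720 + 1)
        assert cm.p.iloc[0, 1] == pytest.approx(expected, abs=1e-9)
        assert cm.rho.iloc[0, 1] == pytest.approx(rho)


class TestBHAdjust:
    def test_hand_step_up(self):
        q = network.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert network.bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(40)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(network.bh_adjust(p), q_ref, atol=1e-12)

    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_step_up_properties(self, p):
        q = network.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            network.bh_adjust([0.5, 1.2])


class TestBuildNetwork:
    @staticmethod
    def _cm(rho_val, q_val):
        ids = ["a", "b"]
        rho = pd.DataFrame([[1.0, rho_val], [rho_val, 1.0]], index=ids, columns=ids)
        p = pd.DataFrame([[np.nan, q_val / 2], [q_val / 2, np.nan]], index=ids, columns=ids)
        q = pd.DataFrame([[np.nan, q_val], [q_val, np.nan]], index=ids, columns=ids)
        return network.CorrelationMatrix(ids, rho, p, q, n_samples=20)

    @pytest.mark.parametrize(
        "rho,q,present",
        [(0.70, 0.01, True), (0.59, 0.001, False), (0.70, 0.06, False),
         (0.60, 0.01, True), (-0.65, 0.01, True)],
    )
    def test_edge_thresholds(self, rho, q, present):
        net = network.build_network(self._cm(rho, q))
        assert net.has_edge("a", "b") == present
        if present:
            assert net.edges["a", "b"]["sign"] == ("positive" if rho > 0 else "negative")

    def test_isolates_dropped_unless_kept(self):
        cm = self._cm(0.3, 0.5)
        assert network.build_network(cm).number_of_nodes() == 0
        assert network.build_network(cm, keep_isolates=True).number_of_nodes() == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        x = rng.random((10, 30))
        a = _abund(x)
        cm = network.spearman_matrix(a)
        loose = network.build_network(cm, r_cutoff=0.2, q_cutoff=0.5)
        tight = network.build_network(cm, r_cutoff=0.4, q_cutoff=0.1)
        assert set(tight.edges).issubset(set(loose.edges))


class TestMetrics:
    @pytest.mark.parametrize("n,e,expected", [(37, 121, 6.54), (46, 174, 7.57)])
    def test_average_neighbors_consistency(self, n, e, expected):
        g = nx.gnm_random_graph(n, e, seed=1)
        m = network.network_metrics(g)
        assert m["n_nodes"] == n and m["n_edges"] == e
        assert round(m["average_neighbors"], 2) == expected

    def test_triangle(self):
        m = network.network_metrics(nx.complete_graph(3))
        assert m["average_clustering"] == pytest.approx(1.0)
        assert m["average_path_length"] == pytest.approx(1.0)

    def test_three_node_path(self):
        m = network.network_metrics(nx.path_graph(3))
        assert m["average_clustering"] == pytest.approx(0.0)
        assert m["average_path_length"] == pytest.approx(4 / 3)

    def test_degree_sum_identity(self):
        g = nx.gnm_random_graph(20, 35, seed=2)
        m = network.network_metrics(g)
        assert sum(dict(g.degree).values()) == 2 * m["n_edges"]
        assert m["average_neighbors"] == pytest.approx(2 * m["n_edges"] / m["n_nodes"], abs=1e-12)

    def test_empty_graph_flagged(self):
        m = network.network_metrics(nx.Graph())
        assert m["n_nodes"] == 0 and np.isnan(m["average_neighbors"])


class TestModules:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        assignment, q, table = network.detect_modules(g)
        assert q == pytest.approx(0.5)
        assert assignment["a"] == assignment["b"] == assignment["c"]
        assert assignment["x"] == assignment["y"] == assignment["z"]
        assert assignment["a"] != assignment["x"]
        # each module: density 1, 3 nodes -> score 3
        assert sorted(table["score"]) == [3.0, 3.0]

    def test_single_community_zero_modularity(self):
        assignment, q, _ = network.detect_modules(nx.complete_graph(4))
        assert len(set(assignment.values())) == 1
        assert q == pytest.approx(0.0)

    def test_edgeless_network(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assignment, q, table = network.detect_modules(g)
        assert len(set(assignment.values())) == 3
        assert q == 0.0
        assert (table["score"] == 0).all()

    def test_deterministic(self):
        g = nx.gnm_random_graph(30, 60, seed=5)
        a1, q1, _ = network.detect_modules(g)
        a2, q2, _ = network.detect_modules(g)
        assert a1 == a2 and q1 == q2

    def test_modularity_bounds(self):
        g = nx.gnm_random_graph(25, 50, seed=6)
        _, q, _ = network.detect_modules(g)
        assert -0.5 <= q <= 1.0


class TestHubRanking:
    def test_star_center_first(self):
        g = nx.star_graph(5)
        df = network.hub_ranking(nx.relabel_nodes(g, str))
        assert df.iloc[0]["genus"] == "0"
        assert df.iloc[0]["degree"] == 5

    def test_no_hubs_still_ranked(self):
        g = nx.path_graph(4)
        df = network.hub_ranking(nx.relabel_nodes(g, str), degree_threshold=10)
        assert not df["is_hub"].any()
        assert len(df) == 4
        assert df.attrs["hub_summary"] == "0/4"

    def test_tie_broken_lexicographically(self):
        g = nx.Graph([("b", "c"), ("a", "c")])
        df = network.hub_ranking(g)
        assert list(df["genus"]) == ["c", "a", "b"]
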