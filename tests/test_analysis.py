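"""Similarity gradients, shortest paths, and the path-length ANOVA."""

import numpy as np
import networkx as nx
import pytest
from scipy import stats

from semwalk import (
    WalkConfig,
    anova_oneway,
    gradient_over_traces,
    iri_by_pathlength,
    min_path_lengths,
    similarity_gradient,
)
from semwalk.analysis import AnalysisError
from semwalk.netbuild import SemanticNetwork
from semwalk.walker import WalkTrace

from conftest import make_matrix


@pytest.fixture()
def two_cluster_matrix():
    """6 items in two tight clusters: within JSD 0.1, between 0.9."""
    v = np.full((6, 6), 0.9)
    v[:3, :3] = 0.1
    v[3:, 3:] = 0.1
    np.fill_diagonal(v, 0.0)
    return make_matrix(v, ids=list("abcdef"))


class TestAnovaOneway:
    def test_hand_computed_example(self):
        f, df1, df2, p = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)  # SSB = 6, SSW = 6
        assert (df1, df2) == (2, 6)

    def test_identical_groups_give_zero(self):
        f, _, _, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agrees_with_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(loc, 1.0, size=rng.integers(5, 30))
                  for loc in (0.0, 0.4, 1.1)]
        f, df1, df2, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1.0, 12) for m in (0, 1, 2)]
        f0, *_ = anova_oneway(groups)
        f1, *_ = anova_oneway([g + 100.0 for g in groups])
        f2, *_ = anova_oneway([g * 3.5 for g in groups])
        assert f1 == pytest.approx(f0)
        assert f2 == pytest.approx(f0)

    def test_small_groups_rejected(self):
        with pytest.raises(AnalysisError):
            anova_oneway([[1.0], [2.0, 3.0]])
        with pytest.raises(AnalysisError):
            anova_oneway([[1.0, 2.0]])


class TestMinPathLengths:
    def test_path_graph_endpoints(self):
        net = SemanticNetwork(nx.path_graph(4))
        assert min_path_lengths(net, [(0, 3), (1, 2), (0, 0)]) == [3, 1, 0]

    def test_unreachable_reported_missing(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b")])
        g.add_node("island")
        net = SemanticNetwork(g)
        assert min_path_lengths(net, [("a", "island")]) == [None]

    def test_unknown_node_rejected(self):
        net = SemanticNetwork(nx.path_graph(3))
        with pytest.raises(AnalysisError, match="ghost"):
            min_path_lengths(net, [(0, "ghost")])

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_floyd_warshall_oracle(self, seed):
        g = nx.gnp_random_graph(50, 0.08, seed=seed)
        net = SemanticNetwork(g)
        rng = np.random.default_rng(seed)
        pairs = [tuple(rng.integers(0, 50, 2)) for _ in range(60)]
        got = min_path_lengths(net, pairs)
        fw = nx.floyd_warshall(g)
        for (a, b), d in zip(pairs, got):
            expect = fw[a][b]
            assert d == (None if np.isinf(expect) else int(expect))


class TestSimilarityGradient:
    def test_degenerate_matrix_rejected(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        # include the diagonal's own pairs only: all off-diagonal equal
        m = make_matrix(v)
        with pytest.raises(AnalysisError, match="degenerate"):
            similarity_gradient(["d0", "d1", "d2", "d3"], m, max_lag=2)

    def test_clustered_sequence_shows_gradient(self, two_cluster_matrix):
        res = similarity_gradient(list("abcdef"), two_cluster_matrix, max_lag=5)
        assert res.mean_z[0] < res.mean_z[4]  # lag 1 more similar than lag 5
        # oracle: z-scores enumerated directly
        pool = []
        for i in range(6):
            for j in range(i + 1, 6):
                pool.append(two_cluster_matrix.values[i, j])
        mu, sd = np.mean(pool), np.std(pool)
        lag1 = np.mean([(two_cluster_matrix.values[i, i + 1] - mu) / sd
                        for i in range(5)])
        assert res.mean_z[0] == pytest.approx(lag1, abs=1e-12)
        assert res.n_pairs == [5, 4, 3, 2, 1]

    def test_sequence_too_short_rejected(self, two_cluster_matrix):
        with pytest.raises(AnalysisError):
            similarity_gradient(list("ab"), two_cluster_matrix, max_lag=5)

    def test_walker_gradient_structured_vs_scrambled(
        self, topic_walks, topic_scrambled_walks, topic_matrix
    ):
        structured = gradient_over_traces(topic_walks, topic_matrix, max_lag=10)
        rho = stats.spearmanr(structured.lags, structured.mean_z).statistic
        assert rho > 0  # diminishing similarity with lag
        assert structured.mean_z[0] < 0  # adjacent retrievals more similar

        control = gradient_over_traces(topic_scrambled_walks, topic_matrix,
                                       max_lag=10)
        assert all(abs(z) < 0.1 for z in control.mean_z)  # flat


def constant_iri_traces(network, iri=2):
    """Hand-built traces whose consecutive retrievals alternate between
    ring-distance 2 and 1 on a path graph (lengths 1 and 2 both occur)."""
    nodes = network.node_ids
    traces = []
    for start in (0, 3):
        offsets = (0, 2, 3, 5, 6)
        ids = [nodes[start + o] for o in offsets]
        traces.append(WalkTrace(
            retrieved_ids=ids,
            hop_iris=[iri] * len(ids),
            degree_iris=[iri * 2] * len(ids),
            steps_total=iri * len(ids),
            config=WalkConfig(n_retrievals=len(ids), seed=0),
            network_provenance="synthetic",
        ))
    return traces


class TestIriByPathLength:
    def test_identical_iris_give_zero_f(self):
        net = SemanticNetwork(nx.path_graph(10))
        traces = constant_iri_traces(net)
        res = iri_by_pathlength(traces, net, max_length=4, aggregate="pooled")
        assert res.f_stat == 0.0

    def test_structured_network_shows_pathlength_effect(
        self, topic_walks, topic_network
    ):
        res = iri_by_pathlength(topic_walks, topic_network, max_length=4)
        assert res.p_value < 0.01
        means = [g.mean() for g in res.log_iris_by_length]
        rho = stats.spearmanr(res.lengths, means).statistic
        assert rho > 0
        assert res.df_between == len(res.lengths) - 1

    def test_control_pathlengths_compressed_vs_structured(
        self, full_control_traces, full_control_network,
        full_semantic_traces, full_semantic_network,
    ):
        # the structural signature that separates the conditions: on the
        # random control, consecutive retrievals are never more than 3 hops
        # apart (small-world compression), while the clustered network
        # spreads them out to 5+ with a heavy right tail
        def consecutive_lengths(traces, net):
            pairs = []
            for t in traces[:10]:
                ids = t.retrieved_ids
                pairs.extend((ids[k - 1], ids[k]) for k in range(1, len(ids)))
            return np.array([
                d for d in min_path_lengths(net, pairs) if d is not None
            ])

        ctrl = consecutive_lengths(full_control_traces, full_control_network)
        sem = consecutive_lengths(full_semantic_traces, full_semantic_network)
        assert ctrl.max() <= 3
        assert sem.max() >= 5
        assert 0.9 <= np.mean(sem <= 4) < 1.0  # a few percent beyond 4

    def test_empty_length_groups_dropped(self):
        # retrievals alternate between adjacent (length 1) and two-apart
        # (length 2) nodes; lengths 3 and 4 never occur and are dropped
        net = SemanticNetwork(nx.path_graph(10))
        ids = [0, 1, 3, 4, 6]
        trace = WalkTrace(
            retrieved_ids=ids,
            hop_iris=[1, 2, 1, 3, 2],
            degree_iris=[2, 4, 2, 6, 4],
            steps_total=9,
            config=WalkConfig(n_retrievals=5, seed=0),
        )
        res = iri_by_pathlength([trace], net, max_length=4, aggregate="pooled")
        assert res.lengths == [1, 2]
        assert res.df_between == 1

    def test_single_length_group_rejected(self):
        net = SemanticNetwork(nx.complete_graph(12))  # all lengths are 1
        traces = constant_iri_traces(net)
        with pytest.raises(AnalysisError, match="fewer than 2"):
            iri_by_pathlength(traces, net, max_length=4, aggregate="pooled")

    def test_measure_and_aggregate_validation(self, topic_walks, topic_network):
        with pytest.raises(AnalysisError):
            iri_by_pathlength(topic_walks, topic_network, max_length=1)
        with pytest.raises(AnalysisError):
            iri_by_pathlength(topic_walks, topic_network, aggregate="bogus")
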