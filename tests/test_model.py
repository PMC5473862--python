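import numpy as np
import pytest
from sklearn.base import clone

from heteropath import (
    ClassifierConfig,
    ConfigError,
    FeatureTable,
    HeteroNetwork,
    LabeledPairSet,
    MetaPathFeaturizer,
    NodeLookupError,
    PairClassifier,
    SamplingError,
    SchemaError,
    TrainingError,
    build_feature_table,
    canonical_feature_paths,
    hetesim_pair,
    parse_metapath,
    rank_candidate_proteins,
    sample_training_pairs,
    score_pairs,
    train_classifier,
)
from helpers import random_lp_network

LP = frozenset("LP")


@pytest.fixture
def small_net(rng):
    return random_lp_network(rng, n_l=6, n_p=5, density=0.5)


class TestBuildFeatureTable:
    def test_damping_scales_by_nodes_beyond_two(self, small_net):
        paths = [parse_metapath(n, LP) for n in ["LLP", "LLPP", "LLLLP"]]
        pair = ("l0", "p0")
        table = build_feature_table(small_net, [pair], paths, beta=0.5)
        raw = [hetesim_pair(small_net, p, *pair) for p in paths]
        assert table.values[0] == pytest.approx(
            [0.5 * raw[0], 0.25 * raw[1], 0.125 * raw[2]]
        )

    def test_beta_one_gives_raw_scores(self, small_net):
        paths = canonical_feature_paths()
        pairs = [("l0", "p1"), ("l3", "p2")]
        table = build_feature_table(small_net, pairs, paths, beta=1.0)
        for i, pair in enumerate(pairs):
            for j, path in enumerate(paths):
                assert table.values[i, j] == pytest.approx(
                    hetesim_pair(small_net, path, *pair), abs=1e-12
                )

    def test_batched_and_per_pair_routes_agree(self, small_net):
        paths = canonical_feature_paths()
        pairs = [(l, p) for l in small_net.node_ids("L") for p in small_net.node_ids("P")]
        batched = build_feature_table(small_net, pairs, paths, beta=0.2)
        for i in (0, 7, 29):
            single = build_feature_table(small_net, [pairs[i]], paths, beta=0.2)
            assert np.allclose(batched.values[i], single.values[0], atol=1e-12)

    def test_column_order_follows_the_manifest(self, small_net):
        table = build_feature_table(
            small_net, [("l0", "p0")], canonical_feature_paths(), beta=0.2
        )
        assert table.columns == [p.name for p in canonical_feature_paths()]

    def test_unknown_pair_id_raises(self, small_net):
        with pytest.raises(NodeLookupError):
            build_feature_table(
                small_net, [("nope", "p0")], canonical_feature_paths(), beta=0.2
            )

    def test_lowering_beta_never_raises_long_path_features(self, small_net):
        paths = canonical_feature_paths()
        pairs = [("l1", "p1"), ("l2", "p3")]
        high = build_feature_table(small_net, pairs, paths, beta=0.7).values
        low = build_feature_table(small_net, pairs, paths, beta=0.3).values
        long_cols = [j for j, p in enumerate(paths) if p.node_count > 3]
        assert np.all(low[:, long_cols] <= high[:, long_cols] + 1e-15)


class TestFeaturizerEstimator:
    def test_sklearn_clone_and_params(self, small_net):
        featurizer = MetaPathFeaturizer(network=small_net, beta=0.3)
        cloned = clone(featurizer)
        assert cloned.get_params()["beta"] == 0.3
        cloned.set_params(beta=0.5).fit()
        assert cloned.feature_names_ == [p.name for p in canonical_feature_paths()]

    def test_mixed_endpoint_paths_rejected(self, small_net):
        bad = [parse_metapath("LLP", LP), parse_metapath("LPL", LP)]
        with pytest.raises(ConfigError):
            MetaPathFeaturizer(network=small_net, paths=bad).fit()


class TestSampling:
    def test_exhaustive_positive_draw_equals_edge_set(self, small_net):
        adj = small_net.relation("L", "P")
        n_edges = int(np.count_nonzero(adj))
        labeled = sample_training_pairs(small_net, small_net, n_edges, 1, seed=0)
        positives = {(l, p) for l, p, y in labeled.pairs if y == 1}
        lnc, prot = small_net.node_ids("L"), small_net.node_ids("P")
        expected = {(lnc[i], prot[j]) for i, j in zip(*np.nonzero(adj))}
        assert positives == expected

    def test_same_seed_reproduces_the_sample(self, small_net):
        a = sample_training_pairs(small_net, small_net, 5, 5, seed=42)
        b = sample_training_pairs(small_net, small_net, 5, 5, seed=42)
        assert a.pairs == b.pairs

    def test_counts_are_exact(self, small_net):
        labeled = sample_training_pairs(small_net, small_net, 7, 9, seed=1)
        labels = labeled.labels
        assert (labels == 1).sum() == 7 and (labels == 0).sum() == 9

    def test_complete_bipartite_negative_net_is_infeasible(self):
        full = HeteroNetwork(
            {"L": ["l1", "l2"], "P": ["p1", "p2"]}, {("L", "P"): np.ones((2, 2))}
        )
        with pytest.raises(SamplingError, match="non-edges"):
            sample_training_pairs(full, full, 1, 1, seed=0)

    def test_mandatory_positives_are_included(self, small_net):
        adj = small_net.relation("L", "P")
        lnc, prot = small_net.node_ids("L"), small_net.node_ids("P")
        i, j = next(zip(*np.nonzero(adj)))
        gold = (lnc[i], prot[j])
        labeled = sample_training_pairs(
            small_net, small_net, 3, 3, seed=5, mandatory_positives=[gold]
        )
        assert (*gold, 1) in labeled.pairs

    def test_mandatory_non_edge_rejected(self, small_net):
        adj = small_net.relation("L", "P")
        lnc, prot = small_net.node_ids("L"), small_net.node_ids("P")
        i, j = next(zip(*np.nonzero(adj == 0)))
        with pytest.raises(SamplingError, match="mandatory"):
            sample_training_pairs(
                small_net, small_net, 3, 3, seed=5,
                mandatory_positives=[(lnc[i], prot[j])],
            )

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ConfigError, match="both labels"):
            LabeledPairSet([("l1", "p1", 1), ("l1", "p1", 0)])


def _separable_table(n=20):
    rng = np.random.default_rng(3)
    pairs = [(f"l{i}", f"p{i}") for i in range(n)]
    values = np.vstack(
        [rng.normal(2.0, 0.1, (n // 2, 3)), rng.normal(-2.0, 0.1, (n // 2, 3))]
    )
    labels = LabeledPairSet(
        [(l, p, 1) for l, p in pairs[: n // 2]] + [(l, p, 0) for l, p in pairs[n // 2 :]]
    )
    return FeatureTable(pairs, ["LLP", "LPP", "LLPP"], values), labels


class TestClassifier:
    def test_separable_features_reach_training_accuracy_one(self):
        table, labels = _separable_table()
        clf = train_classifier(table, labels, ClassifierConfig())
        assert np.array_equal(clf.predict(table), labels.labels)
        scored = score_pairs(clf, table)
        signs = [1 if s >= 0 else 0 for _, s in scored]
        assert signs == list(labels.labels)

    def test_single_class_labels_rejected(self):
        table, _ = _separable_table()
        all_pos = LabeledPairSet([(l, p, 1) for l, p in table.pairs])
        with pytest.raises(TrainingError):
            train_classifier(table, all_pos, ClassifierConfig())

    def test_misaligned_rows_rejected(self):
        table, labels = _separable_table()
        reversed_labels = LabeledPairSet(labels.pairs[::-1])
        with pytest.raises(SchemaError):
            train_classifier(table, reversed_labels, ClassifierConfig())

    def test_duplicated_rows_score_identically(self):
        table, labels = _separable_table()
        clf = train_classifier(table, labels, ClassifierConfig())
        doubled = FeatureTable(
            table.pairs + table.pairs,
            table.columns,
            np.vstack([table.values, table.values]),
        )
        scores = clf.decision_function(doubled)
        assert np.array_equal(scores[: len(table.pairs)], scores[len(table.pairs) :])

    def test_permuted_columns_are_a_schema_error(self):
        table, labels = _separable_table()
        clf = train_classifier(table, labels, ClassifierConfig())
        shuffled = FeatureTable(
            table.pairs, table.columns[::-1], table.values[:, ::-1]
        )
        with pytest.raises(SchemaError):
            clf.decision_function(shuffled)

    def test_training_is_deterministic_given_seed(self):
        table, labels = _separable_table()
        config = ClassifierConfig(seed=11)
        a = train_classifier(table, labels, config).decision_function(table)
        b = train_classifier(table, labels, config).decision_function(table)
        assert np.array_equal(a, b)

    def test_sklearn_clone_round_trip(self):
        clf = PairClassifier(C=2.0, kernel="linear")
        assert clone(clf).get_params()["C"] == 2.0

    @pytest.mark.parametrize("beta", [0.0, 1.5])
    def test_config_rejects_out_of_range_beta(self, beta):
        with pytest.raises(ConfigError):
            ClassifierConfig(beta=beta)


class TestRanking:
    def test_protein_sharing_all_neighbors_ranks_first(self):
        # p_twin binds exactly the lncRNAs that l_query's similar partners bind;
        # p_far binds nothing related to l_query.
        ll = np.array(
            [
                [0.0, 1.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        lp = np.array(
            [
                [0.0, 0.0],  # l_query: no direct edge
                [1.0, 0.0],  # its similar partner binds p_twin
                [0.0, 1.0],  # unrelated lncRNA binds p_far
            ]
        )
        pp = np.zeros((2, 2))
        net = HeteroNetwork(
            {"L": ["l_query", "l_sim", "l_other"], "P": ["p_twin", "p_far"]},
            {("L", "L"): ll, ("L", "P"): lp, ("P", "P"): pp},
        )
        paths = [parse_metapath("LLP", LP), parse_metapath("LPP", LP)]
        # feature inspection: l_query reaches p_twin through its similar
        # partner (nonzero LLP feature) and p_far through nothing
        table = build_feature_table(
            net, [("l_query", "p_twin"), ("l_query", "p_far")], paths, beta=0.5
        )
        assert table.values[0].sum() > 0 and table.values[1].sum() == 0
        # a classifier monotone in the path features must rank p_twin first
        training = FeatureTable(
            [("a", "b"), ("c", "d")], [p.name for p in paths], [[0.6, 0.6], [0.0, 0.0]]
        )
        clf = train_classifier(
            training,
            LabeledPairSet([("a", "b", 1), ("c", "d", 0)]),
            ClassifierConfig(kernel="linear", feature_scaling="none"),
        )
        ranked = rank_candidate_proteins(net, clf, "l_query", paths, beta=0.5)
        assert ranked[0][0] == "p_twin"

    def test_single_protein_network(self):
        net = HeteroNetwork(
            {"L": ["l1"], "P": ["p1"]}, {("L", "P"): np.array([[1.0]])}
        )
        table = FeatureTable([("l1", "p1"), ("l1", "p1")], ["LP"], [[1.0], [0.0]])
        labels = LabeledPairSet([("l1", "p1", 1)])
        clf = PairClassifier(kernel="linear").fit(
            np.array([[1.0], [0.0]]), np.array([1, 0])
        )
        ranked = rank_candidate_proteins(net, clf, "l1", [parse_metapath("LP", LP)], 0.5)
        assert len(ranked) == 1 and ranked[0][0] == "p1"

    def test_unknown_lncrna_rejected(self, small_net):
        clf = PairClassifier(kernel="linear").fit(
            np.zeros((4, 14)) + np.arange(4)[:, None], [0, 0, 1, 1]
        )
        with pytest.raises(NodeLookupError):
            rank_candidate_proteins(
                small_net, clf, "absent", canonical_feature_paths(), 0.2
            )
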