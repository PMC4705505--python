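import itertools
import random

import numpy as np
import pytest

from slpc.detect import (
    CandidateComplex,
    DetectorConfig,
    RegressionModel,
    build_training_set,
    detect_complexes,
    enumerate_maximal_cliques,
    filter_cliques,
    grow_clique,
    merge_filter_candidates,
    score_subgraph,
    train_model,
)
from slpc.features import FEATURE_NAMES
from slpc.network_io import ComplexSet, PPINetwork


def _unit_weighted(net: PPINetwork) -> PPINetwork:
    return PPINetwork.from_edges(
        [(u, v, 1.0) for u, v in net.edges()], nodes=net.nodes, weighted=True
    )


def _density_model(coeff: float = 1.0) -> RegressionModel:
    """Stub scorer: coeff * density, everything else ignored."""
    coefs = np.zeros(len(FEATURE_NAMES))
    coefs[FEATURE_NAMES.index("density")] = coeff
    return RegressionModel(coefs, 0.0, FEATURE_NAMES)


def _brute_force_maximal_cliques(net: PPINetwork, min_size: int) -> set[frozenset]:
    nodes = sorted(net.nodes)
    cliques = set()
    for r in range(min_size, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            if all(net.has_edge(a, b) for a, b in itertools.combinations(combo, 2)):
                cliques.add(frozenset(combo))
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
    }


class TestTrainingSet:
    @pytest.fixture
    def planted(self):
        """Two disjoint K4s plus a sparse background path."""
        edges = list(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
        edges += list(itertools.combinations(["b1", "b2", "b3", "b4"], 2))
        edges += [("x0", "x1"), ("x1", "x2"), ("x2", "x3"), ("x3", "x4"),
                  ("x4", "x5"), ("x5", "x6"), ("x0", "a1"), ("x6", "b1")]
        net = PPINetwork.from_edges(edges)
        return net, _unit_weighted(net)

    def test_count_and_labels(self, planted):
        net, wnet = planted
        positives = ComplexSet([{"a1", "a2", "a3", "a4"}, {"b1", "b2", "b3", "b4"}])
        ts = build_training_set(positives, net, wnet, DetectorConfig(seed=5))
        labels = [lab for _, lab in ts]
        assert labels == [1.0, 1.0, 0.0, 0.0]

    def test_deterministic_given_seed(self, planted):
        net, wnet = planted
        positives = ComplexSet([{"a1", "a2", "a3", "a4"}])
        cfg = DetectorConfig(seed=9)
        a = build_training_set(positives, net, wnet, cfg)
        b = build_training_set(positives, net, wnet, cfg)
        assert len(a) == len(b)
        for (xa, la), (xb, lb) in zip(a, b):
            assert np.array_equal(xa, xb) and la == lb

    def test_negatives_never_equal_a_positive(self, planted):
        net, wnet = planted
        positives = ComplexSet([{"a1", "a2", "a3", "a4"}, {"b1", "b2", "b3", "b4"}])
        pos_vectors = {tuple(x) for x, lab in
                       build_training_set(positives, net, wnet,
                                          DetectorConfig(seed=0, negative_ratio=3))
                       if lab == 1.0}
        # a negative identical to a positive would produce an identical
        # feature vector; K4s are the only density-1 size-4 subgraphs here
        negs = [x for x, lab in
                build_training_set(positives, net, wnet,
                                   DetectorConfig(seed=0, negative_ratio=3))
                if lab == 0.0]
        for x in negs:
            assert tuple(x) not in pos_vectors


class TestTrainModel:
    def test_separable_toy_scores_positives_higher(self):
        x_pos = np.zeros(len(FEATURE_NAMES)); x_pos[0] = 1.0
        x_neg = np.zeros(len(FEATURE_NAMES))
        ts = [(x_pos, 1.0), (x_pos, 1.0), (x_neg, 0.0), (x_neg, 0.0)]
        model = train_model(ts, DetectorConfig())
        hi = model.intercept + model.coefficients @ x_pos
        lo = model.intercept + model.coefficients @ x_neg
        assert hi > lo

    def test_matches_independent_normal_equations(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, len(FEATURE_NAMES)))
        y = (rng.random(30) > 0.5).astype(float)
        cfg = DetectorConfig(ridge_alpha=0.1)
        model = train_model(list(zip(X, y)), cfg)
        # independent solve: centered ridge normal equations
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(
            Xc.T @ Xc + cfg.ridge_alpha * np.eye(X.shape[1]), Xc.T @ yc
        )
        assert np.allclose(model.coefficients, beta, atol=1e-8)
        assert model.intercept == pytest.approx(
            y.mean() - float(X.mean(axis=0) @ beta)
        )

    def test_single_class_rejected(self):
        x = np.zeros(len(FEATURE_NAMES))
        with pytest.raises(ValueError):
            train_model([(x, 1.0), (x, 1.0)], DetectorConfig())

    def test_json_round_trip(self, tmp_path):
        model = _density_model(2.5)
        path = str(tmp_path / "model.json")
        model.save(path)
        back = RegressionModel.load(path)
        assert np.array_equal(back.coefficients, model.coefficients)
        assert back.feature_names == model.feature_names
        assert back.intercept == model.intercept


class TestScoreSubgraph:
    def test_zero_coefficients_return_intercept(self, triangle):
        model = RegressionModel(np.zeros(len(FEATURE_NAMES)), 0.7, FEATURE_NAMES)
        s = score_subgraph({"m", "n"}, model, triangle, _unit_weighted(triangle))
        assert s == 0.7

    def test_linearity_in_coefficients(self, triangle):
        wnet = _unit_weighted(triangle)
        s1 = score_subgraph({"m", "n", "x"}, _density_model(1.0), triangle, wnet)
        s2 = score_subgraph({"m", "n", "x"}, _density_model(2.0), triangle, wnet)
        assert s2 == pytest.approx(2 * s1)

    def test_matches_manual_dot_product(self, triangle):
        from slpc.features import extract_features

        rng = np.random.default_rng(3)
        coefs = rng.normal(size=len(FEATURE_NAMES))
        model = RegressionModel(coefs, 0.25, FEATURE_NAMES)
        wnet = _unit_weighted(triangle)
        expected = 0.25 + coefs @ extract_features({"m", "n", "x"}, triangle, wnet)
        assert score_subgraph({"m", "n", "x"}, model, triangle, wnet) == pytest.approx(expected)

    def test_registry_mismatch_rejected(self, triangle):
        model = RegressionModel(np.zeros(2), 0.0, ("density", "other"))
        with pytest.raises(ValueError, match="registry"):
            score_subgraph({"m", "n"}, model, triangle, _unit_weighted(triangle))


class TestCliqueEnumeration:
    def test_k4_yields_single_clique(self):
        k4 = PPINetwork.from_edges(itertools.combinations("abcd", 2))
        assert enumerate_maximal_cliques(k4, 3) == [frozenset("abcd")]

    def test_path_has_no_triangles(self):
        path = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        assert enumerate_maximal_cliques(path, 3) == []

    def test_matches_brute_force_on_random_graphs(self):
        import networkx as nx

        rng = random.Random(31)
        for _ in range(30):
            g = nx.gnp_random_graph(9, 0.5, seed=rng.randint(0, 10**6))
            net = PPINetwork.from_edges(
                [(f"p{u}", f"p{v}") for u, v in g.edges],
                nodes=[f"p{i}" for i in range(9)],
            )
            expected = {
                c for c in _brute_force_maximal_cliques(net, 3)
            }
            assert set(enumerate_maximal_cliques(net, 3)) == expected

    def test_output_order_deterministic(self):
        net = PPINetwork.from_edges(
            list(itertools.combinations("abc", 2))
            + list(itertools.combinations("defg", 2))
        )
        cliques = enumerate_maximal_cliques(net, 3)
        assert cliques == [frozenset("defg"), frozenset("abc")]


class TestFilterCliques:
    def test_identical_cliques_collapse(self, triangle):
        model = _density_model()
        wnet = _unit_weighted(triangle)
        out = filter_cliques(
            [frozenset("mnx"), frozenset("mnx")], model, DetectorConfig(),
            triangle, wnet,
        )
        assert len(out) == 1

    def test_disjoint_cliques_both_survive(self):
        net = PPINetwork.from_edges(
            list(itertools.combinations("abc", 2))
            + list(itertools.combinations("def", 2))
        )
        out = filter_cliques(
            enumerate_maximal_cliques(net, 3), _density_model(),
            DetectorConfig(clique_overlap_thred=0.99), net, _unit_weighted(net),
        )
        assert {c.members for c in out} == {frozenset("abc"), frozenset("def")}

    def test_overlapping_lower_scorer_removed(self):
        # {a,b,c} forms a triangle (density 1); {b,c,d} is missing one edge
        net = PPINetwork.from_edges(
            [("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")]
        )
        cliques = [frozenset("abc"), frozenset("bcd")]
        out = filter_cliques(
            cliques, _density_model(), DetectorConfig(clique_overlap_thred=0.5),
            net, _unit_weighted(net),
        )
        # overlap ratio 2/3 > 0.5 and density({b,c,d}) = 2/3 < 1
        assert [c.members for c in out] == [frozenset("abc")]


class TestGrowClique:
    def test_no_neighbors_unchanged(self, triangle):
        model = _density_model()
        cand = CandidateComplex(
            frozenset("mnx"),
            score_subgraph(frozenset("mnx"), model, triangle, _unit_weighted(triangle)),
        )
        grown = grow_clique(cand, model, triangle, _unit_weighted(triangle))
        assert grown.members == cand.members

    def test_strict_increase_required(self):
        # triangle inside K4: adding the 4th node keeps density at 1,
        # which is NOT a strict increase, so the triangle stays put
        k4 = PPINetwork.from_edges(itertools.combinations("abcd", 2))
        model = _density_model()
        start = frozenset("abc")
        cand = CandidateComplex(
            start, score_subgraph(start, model, k4, _unit_weighted(k4))
        )
        grown = grow_clique(cand, model, k4, _unit_weighted(k4))
        assert grown.members == start

    def test_growth_follows_score_gradient(self):
        # weight-sum model: absorbing any neighbor adds weight, so the
        # candidate swallows its whole connected component
        net = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        coefs = np.zeros(len(FEATURE_NAMES))
        coefs[FEATURE_NAMES.index("weight_sum")] = 1.0
        model = RegressionModel(coefs, 0.0, FEATURE_NAMES)
        wnet = _unit_weighted(net)
        start = frozenset("abc")
        cand = CandidateComplex(start, score_subgraph(start, model, net, wnet))
        grown = grow_clique(cand, model, net, wnet)
        assert grown.members == frozenset("abcd")
        assert grown.score > cand.score


class TestMergeFilter:
    def test_disjoint_candidates_all_retained(self):
        net = PPINetwork.from_edges(
            list(itertools.combinations("abc", 2))
            + list(itertools.combinations("def", 2))
        )
        model = _density_model()
        wnet = _unit_weighted(net)
        cands = [
            CandidateComplex(frozenset("abc"), 1.0),
            CandidateComplex(frozenset("def"), 0.9),
        ]
        out = merge_filter_candidates(cands, model, DetectorConfig(), net, wnet)
        assert {frozenset(c) for c in out} == {frozenset("abc"), frozenset("def")}

    def test_identical_candidates_collapse(self, triangle):
        model = _density_model()
        cands = [CandidateComplex(frozenset("mnx"), 1.0)] * 2
        out = merge_filter_candidates(
            cands, model, DetectorConfig(), triangle, _unit_weighted(triangle)
        )
        assert len(out) == 1

    def test_worse_overlapping_candidate_removed_when_union_does_not_improve(self):
        # A={a,b,c} dense, B={b,c,d} sparse; union density drops, so B goes
        net = PPINetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")])
        model = _density_model()
        wnet = _unit_weighted(net)
        a = frozenset("abc")
        b = frozenset("bcd")
        cands = [
            CandidateComplex(a, score_subgraph(a, model, net, wnet)),
            CandidateComplex(b, score_subgraph(b, model, net, wnet)),
        ]
        out = merge_filter_candidates(
            cands, model, DetectorConfig(merg_thred=0.25), net, wnet
        )
        assert [frozenset(c) for c in out] == [a]

    def test_merge_when_union_scores_higher(self):
        # weight-sum model rewards unions of overlapping candidates
        net = PPINetwork.from_edges(itertools.combinations("abcd", 2))
        coefs = np.zeros(len(FEATURE_NAMES))
        coefs[FEATURE_NAMES.index("weight_sum")] = 1.0
        model = RegressionModel(coefs, 0.0, FEATURE_NAMES)
        wnet = _unit_weighted(net)
        a, b = frozenset("abc"), frozenset("bcd")
        cands = [
            CandidateComplex(a, score_subgraph(a, model, net, wnet)),
            CandidateComplex(b, score_subgraph(b, model, net, wnet)),
        ]
        out = merge_filter_candidates(
            cands, model, DetectorConfig(merg_thred=0.25), net, wnet
        )
        assert [frozenset(c) for c in out] == [frozenset("abcd")]


class TestDetectPipeline:
    def test_two_disjoint_k5s_recovered_exactly(self):
        edges = list(itertools.combinations([f"a{i}" for i in range(5)], 2))
        edges += list(itertools.combinations([f"b{i}" for i in range(5)], 2))
        net = PPINetwork.from_edges(edges)
        pred = detect_complexes(net, _unit_weighted(net), _density_model())
        assert {frozenset(c) for c in pred} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_edgeless_network_predicts_nothing(self):
        net = PPINetwork.from_edges([], nodes=["a", "b", "c"])
        pred = detect_complexes(net, _unit_weighted(net), _density_model())
        assert len(pred) == 0

    def test_predictions_induce_connected_subgraphs(self):
        import networkx as nx

        rng = random.Random(41)
        g = nx.gnp_random_graph(25, 0.25, seed=7)
        net = PPINetwork.from_edges(
            [(f"p{u:02d}", f"p{v:02d}") for u, v in g.edges],
            nodes=[f"p{i:02d}" for i in range(25)],
        )
        pred = detect_complexes(net, _unit_weighted(net), _density_model())
        for c in pred:
            assert nx.is_connected(net.subgraph(c))

    def test_rerun_is_identical(self):
        import networkx as nx

        g = nx.gnp_random_graph(20, 0.3, seed=8)
        net = PPINetwork.from_edges([(f"p{u}", f"p{v}") for u, v in g.edges])
        model = _density_model()
        a = detect_complexes(net, _unit_weighted(net), model)
        b = detect_complexes(net, _unit_weighted(net), model)
        assert a.complexes == b.complexes and a.scores == b.scores
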