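import math

import numpy as np
import pytest

import _oracles as oracle
from stancenet import metrics as mx
from stancenet.layers import build_multilayer, flatten
from stancenet.synthetic import ForumConfig, generate_corpus, generate_users

from conftest import network_from_triples, record


class TestDegree:
    def test_star_indegree(self):
        M = network_from_triples([(f"u{i}", "hub", "P") for i in range(5)])
        assert mx.degree(M, "hub", "P", "in") == 5
        assert mx.degree(M, "hub", "P", "out") == 0

    def test_absent_node_has_zero_degree_everywhere(self):
        M = network_from_triples([("a", "b", "P")])
        for layer in "PHA":
            for direction in ("in", "out"):
                assert mx.degree(M, "ghost", layer, direction) == 0

    def test_repeat_comments_count_one_neighbor(self):
        M = build_multilayer([record("u", "v", "H", minutes=1), record("u", "v", "H", minutes=2)])
        assert mx.degree(M, "v", "H", "in") == 1


class TestCrossDegree:
    def test_same_neighbor_in_two_layers_counted_once(self):
        M = network_from_triples([("u", "v", "P"), ("u", "v", "H")])
        assert mx.cross_degree(M, "v", "in") == 1

    def test_disjoint_neighbor_sets_add_up(self):
        triples = (
            [(f"p{i}", "v", "P") for i in range(2)]
            + [(f"h{i}", "v", "H") for i in range(3)]
            + [("a0", "v", "A")]
        )
        assert mx.cross_degree(network_from_triples(triples), "v", "in") == 6

    def test_degree_sandwich_on_random_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            triples = oracle.random_triples(rng)
            M = network_from_triples(triples)
            for v in M.nodes():
                for direction in ("in", "out"):
                    per_layer = [mx.degree(M, v, l, direction) for l in "PHA"]
                    cross = mx.cross_degree(M, v, direction)
                    assert max(per_layer) <= cross <= sum(per_layer)


class TestLayerDiversity:
    def test_single_layer_network_degenerates_to_mean_degree(self):
        triples = [("a", "b", "P"), ("c", "b", "P"), ("a", "c", "P")]
        M = network_from_triples(triples)
        nodes = list(M.layers["P"].nodes)
        expected = np.mean([mx.degree(M, v, "P", "in") for v in nodes])
        assert mx.layer_diversity(M, "P", "in") == pytest.approx(expected)

    def test_empty_layer_is_nan(self):
        M = network_from_triples([("a", "b", "P")])
        assert math.isnan(mx.layer_diversity(M, "A", "in"))

    def test_fully_chambered_synthetic_equals_within_layer_mean(self):
        # no spanners, chambering 1, no boos: every user is single-layer, so
        # the cross-degree union degenerates to the within-layer neighbor set
        cfg = ForumConfig(
            n_users=400,
            n_posts_per_layer=(15, 15, 15),
            chambering=1.0,
            spanner_fraction=0.0,
            boo_rate=0.0,
            n_periods=2,
            seed=13,
        )
        posts = generate_corpus(cfg, generate_users(cfg))
        M = build_multilayer(flatten(posts, seed=0))
        for layer in "PHA":
            nodes = list(M.layers[layer].nodes)
            for direction in ("in", "out"):
                within = np.mean([mx.degree(M, v, layer, direction) for v in nodes])
                assert mx.layer_diversity(M, layer, direction) == pytest.approx(within)


class TestSpearman:
    def test_identical_and_reversed_rankings(self):
        # P and H share a,b,c with identical in-degrees -> rho = 1
        triples = []
        for layer in ("P", "H"):
            triples += [(f"x{i}{layer}", "a", layer) for i in range(3)]
            triples += [(f"y{i}{layer}", "b", layer) for i in range(2)]
            triples += [(f"z{layer}", "c", layer)]
        M = network_from_triples(triples)
        assert mx.spearman_pair(M, "P", "H", "in") == pytest.approx(1.0)

    def test_toy_vectors_match_rank_then_pearson(self):
        assert oracle.spearman([3, 1, 2], [2, 1, 3]) == pytest.approx(0.5)
        triples = (
            [(f"p{i}", "a", "P") for i in range(3)]
            + [("p0", "b", "P")]
            + [(f"q{i}", "c", "P") for i in range(2)]
            + [(f"h{i}", "a", "H") for i in range(2)]
            + [("h0", "b", "H")]
            + [(f"g{i}", "c", "H") for i in range(3)]
        )
        M = network_from_triples(triples)
        # in-degrees on common nodes a,b,c: P=(3,1,2), H=(2,1,3)
        assert mx.spearman_pair(M, "P", "H", "in") == pytest.approx(0.5)

    def test_too_few_common_nodes_is_nan(self):
        M = network_from_triples([("a", "b", "P"), ("c", "d", "H")])
        assert math.isnan(mx.spearman_pair(M, "P", "H", "in"))

    def test_zero_variance_is_nan(self):
        triples = [("u", "a", "P"), ("u", "b", "P"), ("w", "a", "H"), ("x", "b", "H"), ("y", "b", "H")]
        M = network_from_triples(triples)
        assert math.isnan(mx.spearman_pair(M, "P", "H", "in"))


class TestOverlap:
    def test_identical_and_disjoint_node_sets(self):
        M = network_from_triples([("a", "b", "P"), ("a", "b", "H")])
        assert mx.overlap(M, "P", "H") == 100.0
        M2 = network_from_triples([("a", "b", "P"), ("c", "d", "H")])
        assert mx.overlap(M2, "P", "H") == 0.0

    def test_jaccard_percentage(self):
        # V^P = {1,2,3}, V^H = {3,4}: 1 common node, union of 4 -> 25%
        M = network_from_triples([("1", "2", "P"), ("2", "3", "P"), ("3", "4", "H")])
        assert mx.overlap(M, "P", "H") == pytest.approx(25.0)

    def test_alternative_denominators(self):
        M = network_from_triples([("1", "2", "P"), ("2", "3", "P"), ("3", "4", "H")])
        assert mx.overlap(M, "P", "H", denominator="min") == pytest.approx(50.0)
        assert mx.overlap(M, "P", "H", denominator="sum") == pytest.approx(20.0)
        assert mx.overlap(M, "P", "H", denominator="a") == pytest.approx(100 / 3)

    def test_empty_layers_nan(self):
        M = network_from_triples([("a", "b", "P")])
        assert math.isnan(mx.overlap(M, "H", "A"))


class TestEntropy:
    def test_single_layer_node_has_zero_entropy(self):
        M = network_from_triples([("u", "v", "P")])
        assert mx.entropy(M, "u") == 0.0

    def test_even_three_way_spread_reaches_ln3(self):
        M = network_from_triples([("u", "v", "P"), ("u", "v", "H"), ("u", "v", "A")])
        assert mx.entropy(M, "u") == pytest.approx(math.log(3))

    def test_half_quarter_quarter_split(self):
        # p = (1/2, 1/4, 1/4) -> 1.5 ln 2
        triples = (
            [(f"p{i}", "u", "P") for i in range(2)]
            + [("h0", "u", "H")]
            + [("a0", "u", "A")]
        )
        M = network_from_triples(triples)
        assert mx.entropy(M, "u") == pytest.approx(1.5 * math.log(2))

    def test_isolated_node_is_nan(self):
        M = network_from_triples([("a", "b", "P")])
        assert math.isnan(mx.entropy(M, "ghost"))

    def test_comment_count_variant(self):
        M = build_multilayer(
            [record("u", "v", "P", minutes=1), record("u", "v", "P", minutes=2), record("u", "w", "H")]
        )
        # neighbor counts: P=1, H=1 -> ln 2; comment counts: P=2, H=1
        assert mx.entropy(M, "u") == pytest.approx(math.log(2))
        p = np.array([2 / 3, 1 / 3])
        assert mx.entropy(M, "u", use_comment_counts=True) == pytest.approx(
            float(-(p * np.log(p)).sum())
        )


class TestSelections:
    def test_hardliners_prefer_low_entropy_then_activity(self):
        triples = []
        # one cross-layer node (positive entropy), five single-layer nodes
        # with within-P activity 6 > 5 > 4 > 3 > 2
        for i, n in enumerate([6, 5, 4, 3, 2]):
            triples += [(f"s{i}", f"t{j}{i}", "P") for j in range(n)]
        triples += [("mix", f"m{j}", "P") for j in range(8)]
        triples += [("mix", "q", "H")]
        M = network_from_triples(triples)
        got = mx.select_hardliners(M, "P", k=3, min_activity=1)
        assert got == ["s0", "s1", "s2"]

    def test_k_larger_than_pool_returns_pool(self):
        M = network_from_triples([("a", "b", "P")])
        assert set(mx.select_hardliners(M, "P", k=30, min_activity=1)) == {"a", "b"}

    def test_min_activity_floor_filters_one_comment_users(self):
        triples = [("busy", f"t{j}", "P") for j in range(10)] + [("once", "busy", "P")]
        M = network_from_triples(triples)
        assert mx.select_hardliners(M, "P", k=30, min_activity=5) == ["busy"]

    def test_diverse_selects_star_hub(self):
        M = network_from_triples([(f"u{i}", "hub", "P") for i in range(5)])
        assert mx.select_diverse(M, k=1) == ["hub"]

    def test_diverse_matches_exhaustive_sort(self):
        rng = np.random.default_rng(5)
        triples = oracle.random_triples(rng, max_nodes=10, max_records=35)
        M = network_from_triples(triples)
        key = lambda v: (
            -(oracle.cross_degree(triples, v, "in") + oracle.cross_degree(triples, v, "out")),
            -oracle.entropy(triples, v),
            v,
        )
        expected = sorted(sorted({n for t in triples for n in t[:2]}), key=key)[:4]
        assert mx.select_diverse(M, k=4) == expected

    def test_equal_degrees_fall_back_to_id_order(self):
        M = network_from_triples([("a", "b", "P"), ("c", "d", "P")])
        assert mx.select_diverse(M, k=2) == ["a", "b"]


class TestLayerProportions:
    def test_all_in_one_layer(self):
        M = network_from_triples([("u", "v", "P")])
        props = mx.layer_proportions(M, ["v"], "in")
        assert props == {"P": 100.0, "H": 0.0, "A": 0.0}

    def test_direct_arithmetic(self):
        triples = (
            [(f"p{i}", "u", "P") for i in range(5)]
            + [(f"h{i}", "u", "H") for i in range(3)]
            + [(f"a{i}", "u", "A") for i in range(2)]
        )
        props = mx.layer_proportions(network_from_triples(triples), ["u"], "in")
        assert (props["P"], props["H"], props["A"]) == (50.0, 30.0, 20.0)

    def test_proportions_sum_to_100_on_random_toys(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            triples = oracle.random_triples(rng)
            M = network_from_triples(triples)
            nodes = mx.select_diverse(M, k=5)
            props = mx.layer_proportions(M, nodes, "out")
            if not math.isnan(props["P"]):
                assert sum(props.values()) == pytest.approx(100.0)


class TestHardlinerDegrees:
    def test_average_node_standardizes_to_one(self):
        # both P nodes have indegree 1 and outdegree 1 -> any choice == mean
        M = network_from_triples([("a", "b", "P"), ("b", "a", "P")])
        std = mx.hardliner_degrees(M, "P", hardliners=["a"])
        assert std == {"out": pytest.approx(1.0), "in": pytest.approx(1.0)}

    def test_four_node_toy_hand_computation(self):
        # P layer: a->b, a->c, d->b. out-degrees (a,b,c,d)=(2,0,0,1), mean 0.75
        # in-degrees (0,2,1,0), mean 0.75
        M = network_from_triples([("a", "b", "P"), ("a", "c", "P"), ("d", "b", "P")])
        std = mx.hardliner_degrees(M, "P", hardliners=["a", "b"])
        assert std["out"] == pytest.approx(((2 / 0.75) + 0) / 2)
        assert std["in"] == pytest.approx((0 + (2 / 0.75)) / 2)

    def test_doubling_hardliner_edges_doubles_standardized_mean(self):
        base = [("hl", "t0", "P"), ("x", "y", "P"), ("y", "x", "P"), ("x", "t0", "P")]
        doubled = base + [("hl", "t1", "P"), ("hl", "t2", "P")]
        # keep the layer mean fixed by rescaling against the base layer mean
        M1, M2 = network_from_triples(base), network_from_triples(doubled)
        nodes1 = list(M1.layers["P"].nodes)
        mean_out_1 = np.mean([mx.degree(M1, v, "P", "out") for v in nodes1])
        raw1 = mx.degree(M1, "hl", "P", "out") / mean_out_1
        raw2 = mx.degree(M2, "hl", "P", "out") / mean_out_1
        assert raw2 == pytest.approx(3 * raw1)

    def test_empty_hardliner_set_is_nan(self):
        M = network_from_triples([("a", "b", "P")])
        std = mx.hardliner_degrees(M, "P", hardliners=[])
        assert math.isnan(std["out"]) and math.isnan(std["in"])


class TestMetricSeries:
    def test_single_point_equals_static_value(self, tiny_corpus):
        posts, _ = tiny_corpus
        records = flatten(posts, seed=1)
        T = max(r.time for r in records)
        series = mx.metric_series(records, [T], lambda M: mx.overlap(M, "P", "H"))
        static = mx.overlap(build_multilayer(records), "P", "H")
        assert series.values[0] == pytest.approx(static)

    def test_node_counts_nondecreasing(self, tiny_corpus, tiny_config):
        posts, _ = tiny_corpus
        records = flatten(posts, seed=1)
        series = mx.metric_series(
            records, tiny_config.period_boundaries(), lambda M: len(M.nodes())
        )
        assert list(series.values) == sorted(series.values)

    def test_undefined_points_surface_as_gaps(self):
        records = [record("a", "b", "P", minutes=60)]
        series = mx.metric_series(
            records, [T0_plus(0), T0_plus(120)], lambda M: mx.spearman_pair(M, "P", "H", "in")
        )
        assert np.isnan(series.values).all()
        assert len(series.values) == 2


def T0_plus(minutes):
    from datetime import timedelta

    from conftest import T0

    return T0 + timedelta(minutes=minutes)
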