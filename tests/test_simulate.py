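"""Attribute generation, network simulation, expected edges, and the fixture."""

import math

import numpy as np
import pytest
from scipy.special import expit

from kinergm import (
    ModelSpec,
    ScalarRule,
    edges,
    expected_edges,
    generate_attributes,
    make_avar_fixture,
    nodematch,
    nodemix,
    nodes_for_expected_edges,
    simulate_network,
    simulate_pair_table,
    threshold_network,
)


class TestGenerateAttributes:
    @pytest.mark.parametrize(
        "n,props,counts",
        [
            (300, {"1": 0.5, "2": 0.5}, {"1": 150, "2": 150}),
            (300, {"1": 0.25, "2": 0.75}, {"1": 75, "2": 225}),
            (4, {"a": 0.5, "b": 0.5, "c": 0.0}, {"a": 2, "b": 2, "c": 0}),
        ],
    )
    def test_exact_quotas(self, n, props, counts):
        nt = generate_attributes(
            n, {"g": (list(props), list(props.values()))}, seed=7
        )
        values = nt.attributes["g"]
        assert {l: values.count(l) for l in props} == counts

    def test_remainder_assigned_but_total_exact(self):
        nt = generate_attributes(10, {"g": (["a", "b", "c"], [1 / 3] * 3)}, seed=1)
        counts = sorted(nt.attributes["g"].count(l) for l in "abc")
        assert counts in ([3, 3, 4], [2, 4, 4])
        assert sum(counts) == 10

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="below"):
            generate_attributes(2, {"g": (["a", "b", "c"], [0.4, 0.4, 0.2])})

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_attributes(10, {"g": (["a", "b"], [0.6, 0.6])})


class TestSimulateNetwork:
    def test_vanishing_intercept_gives_empty_graph(self):
        nt = generate_attributes(50, {}, seed=0)
        net = simulate_network(nt, ModelSpec([edges()]), [-30.0], seed=1)
        assert net.n_edges == 0

    def test_same_seed_same_edges(self):
        nt = generate_attributes(40, {"sex": (["1", "2"], [0.5, 0.5])}, seed=2)
        spec = ModelSpec([edges(), nodematch("sex")])
        a = simulate_network(nt, spec, [-2.0, 0.5], seed=5)
        b = simulate_network(nt, spec, [-2.0, 0.5], seed=5)
        c = simulate_network(nt, spec, [-2.0, 0.5], seed=6)
        assert a == b
        assert a != c

    def test_dimension_mismatch_rejected(self):
        nt = generate_attributes(10, {}, seed=0)
        with pytest.raises(ValueError, match="entries"):
            simulate_network(nt, ModelSpec([edges()]), [-2.0, 0.5], seed=0)

    def test_disjoint_dyads_uncorrelated(self):
        nt = generate_attributes(6, {}, seed=0)
        spec = ModelSpec([edges()])
        a_list, b_list = [], []
        for r in range(2000):
            net = simulate_network(nt, spec, [0.0], seed=r)
            pairs = net.edge_index_pairs()
            a_list.append((0, 1) in pairs)
            b_list.append((2, 3) in pairs)
        r = np.corrcoef(np.array(a_list, float), np.array(b_list, float))[0, 1]
        assert abs(r) < 0.05


class TestExpectedEdges:
    def test_intercept_only_closed_form(self):
        nt = generate_attributes(300, {}, seed=0)
        expect = expected_edges(nt, ModelSpec([edges()]), [-4.0])
        assert expect == pytest.approx(math.comb(300, 2) * expit(-4.0))
        assert expect == pytest.approx(806.7, abs=0.1)

    @pytest.mark.parametrize("n", [0, 1])
    def test_tiny_networks_have_zero_expectation(self, n):
        nt = generate_attributes(n, {}, seed=0)
        assert expected_edges(nt, ModelSpec([edges()]), [-1.0]) == 0.0

    def test_matches_monte_carlo_mean(self):
        """Simulator and exact expectation agree within 3 SEs over 300 draws."""
        nt = generate_attributes(300, {"sex": (["1", "2"], [0.5, 0.5])}, seed=0)
        spec = ModelSpec([edges(), nodematch("sex")])
        theta = [-4.0, 0.5]
        expect = expected_edges(nt, spec, theta)
        counts = [
            simulate_network(nt, spec, theta, seed=r).n_edges for r in range(300)
        ]
        counts = np.array(counts, float)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_grouped_equals_enumeration(self):
        """Pattern-grouped expectation equals the brute-force dyad sum."""
        from kinergm.dyadmodel import design_matrix

        nt = generate_attributes(
            30,
            {"sex": (["1", "2"], [0.5, 0.5]), "site": (["A", "B", "C"], [0.4, 0.3, 0.3])},
            seed=3,
        )
        spec = ModelSpec([edges(), nodematch("sex"), nodemix("site")])
        theta = np.array([-2.0, 0.5, 0.3, -0.2, 0.8, 0.1, 1.0])
        _, _, X, _, _ = design_matrix(nt, spec)
        brute = expit(X @ theta).sum()
        assert expected_edges(nt, spec, theta) == pytest.approx(brute, rel=1e-12)


class TestNodesForExpectedEdges:
    def test_inverts_intercept_only_expectation(self):
        assert nodes_for_expected_edges(806, ModelSpec([edges()]), [-4.0]) == 300

    def test_single_dyad_threshold(self):
        # at theta0=0, n=2 gives 0.5 expected edges; n=3 gives 1.5
        assert nodes_for_expected_edges(1, ModelSpec([edges()]), [0.0]) == 3

    def test_monotone_in_target(self):
        spec = ModelSpec([edges()])
        ns = [nodes_for_expected_edges(t, spec, [-4.0]) for t in (10, 100, 500, 806)]
        assert ns == sorted(ns)

    def test_unreachable_target(self):
        with pytest.raises(ValueError, match="unreachable"):
            nodes_for_expected_edges(10, ModelSpec([edges()]), [-40.0], n_max=10_000)


class TestAvarFixture:
    def test_shape_and_determinism(self):
        nodes, spec, theta, net = make_avar_fixture(seed=1)
        assert nodes.n == 237
        assert nodes.levels["site"] == ["HNJ", "KFJ", "KUP", "RK"]
        assert len(theta) == spec.n_params(nodes)
        nodes2, _, theta2, net2 = make_avar_fixture(seed=1)
        assert nodes2 == nodes
        assert np.allclose(theta, theta2)
        assert net2 == net
        assert make_avar_fixture(seed=2)[3] != net

    def test_generating_folds_match_published_shape(self):
        from kinergm import fold_change

        nodes, spec, theta, _ = make_avar_fixture(seed=0)
        cols = spec.column_names(nodes)
        folds = {c: fold_change(theta[0], t) for c, t in zip(cols[1:], theta[1:])}
        assert folds["nodematch_diff.site.KFJ"] == pytest.approx(857.0, rel=1e-6)
        assert folds["nodemix.sex_age.AdultM.AdultM"] == pytest.approx(6.62, rel=1e-6)
        assert folds["nodemix.sex_age.AdultF.AdultF"] < 1.0


class TestPairTable:
    def test_thresholding_recovers_a_network(self):
        nodes = generate_attributes(60, {"sex": (["1", "2"], [0.5, 0.5])}, seed=0)
        spec = ModelSpec([edges(), nodematch("sex")])
        pairs = simulate_pair_table(nodes, spec, [-2.0, 1.0], seed=3, base_cutoff=12.0)
        net = threshold_network(pairs, nodes, ScalarRule(12.0))
        assert 0 < net.n_edges < nodes.n * (nodes.n - 1) // 2
        # all recorded sharing is positive and unordered-unique
        keys = [p.key for p in pairs]
        assert len(keys) == len(set(keys))
        assert all(p.total_cm > 0 for p in pairs)
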