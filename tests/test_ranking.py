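"""Sign algebra, sign-constrained path search, receptor scoring/ranking."""

import math

import networkx as nx
import numpy as np
import pytest

from mevrank.errors import EmptyReceptorSetError, MissingNodeError, ValidationError
from mevrank.fixtures import load_curated_network, load_curated_receptors
from mevrank.network import SignalingNetwork, assign_costs, merge_edge_records
from mevrank.ranking import (
    PhenotypeTargets,
    min_cost_signed_path,
    net_sign,
    rank_receptors,
    score_receptor,
)


def build_net(edges):
    """edges: iterable of (u, v, sign, cost)."""
    net = SignalingNetwork()
    for u, v, s, c in edges:
        net.add_edge(u, v, s, provenance="curated", cost=c)
    return net


def random_signed_network(rng, max_nodes=9, allow_unknown=False):
    n = int(rng.integers(4, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    net = SignalingNetwork()
    sign_pool = [-1, 1, 0] if allow_unknown else [-1, 1]
    for u in names:
        for v in names:
            if u != v and rng.random() < 0.35:
                sign = int(rng.choice(sign_pool))
                cost = float(rng.uniform(0.2, 3.0))
                net.add_edge(u, v, sign, cost=cost)
    return net, names


def enumerate_best(net, source, target, required_sign, mode="strict"):
    """Independent oracle: exhaustive enumeration over all simple paths."""
    best = None
    if source not in net.graph or target not in net.graph:
        return None
    for nodes in nx.all_simple_paths(net.graph, source, target):
        signs = [net.sign(a, b) for a, b in zip(nodes, nodes[1:])]
        product = 1
        zeroed = False
        for s in signs:
            if s == 0:
                if mode == "strict":
                    zeroed = True
                    break
                continue
            product *= s
        if zeroed or product != required_sign:
            continue
        cost = sum(net.cost(a, b) for a, b in zip(nodes, nodes[1:]))
        if best is None or cost < best:
            best = cost
    return best


class TestNetSign:
    @pytest.mark.parametrize(
        "signs,mode,expected",
        [
            ((-1, -1), "strict", 1),
            ((1, -1, 1), "strict", -1),
            ((1, 0), "strict", 0),
            ((1, 0), "lenient", 1),
            ((-1, 0, -1), "lenient", 1),
            ((1,), "strict", 1),
        ],
    )
    def test_composition_rules(self, signs, mode, expected):
        assert net_sign(signs, mode) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            net_sign([2])
        with pytest.raises(ValidationError):
            net_sign([])
        with pytest.raises(ValidationError):
            net_sign([1], mode="weird")


class TestPathSearch:
    @pytest.fixture
    def triangle(self):
        # positive 2-hop route vs negative direct route
        return build_net([("A", "B", 1, 1.0), ("B", "T", 1, 1.0), ("A", "T", -1, 3.0)])

    def test_required_positive_takes_two_hop(self, triangle):
        path = min_cost_signed_path(triangle, "A", "T", 1)
        assert path.nodes == ("A", "B", "T")
        assert path.total_cost == pytest.approx(2.0)
        assert path.net_sign == 1

    def test_required_negative_takes_direct(self, triangle):
        path = min_cost_signed_path(triangle, "A", "T", -1)
        assert path.nodes == ("A", "T")
        assert path.total_cost == pytest.approx(3.0)

    def test_unreachable_returns_none(self, triangle):
        triangle.add_node("LONER")
        assert min_cost_signed_path(triangle, "LONER", "T", 1) is None

    def test_missing_node_rejected(self, triangle):
        with pytest.raises(MissingNodeError):
            min_cost_signed_path(triangle, "A", "GHOST", 1)

    def test_source_equals_target_rejected(self, triangle):
        with pytest.raises(ValidationError):
            min_cost_signed_path(triangle, "A", "A", 1)

    @pytest.mark.parametrize("mode,allow_unknown", [("strict", True), ("lenient", True), ("strict", False)])
    def test_matches_exhaustive_enumeration(self, mode, allow_unknown):
        rng = np.random.default_rng(2 * (mode == "lenient") + allow_unknown)
        for _ in range(40):
            net, names = random_signed_network(rng, allow_unknown=allow_unknown)
            source, target = names[0], names[-1]
            if source not in net.graph or target not in net.graph:
                continue
            for required in (1, -1):
                expected = enumerate_best(net, source, target, required, mode)
                got = min_cost_signed_path(net, source, target, required, mode=mode)
                if expected is None:
                    assert got is None
                else:
                    assert got is not None
                    assert got.total_cost == pytest.approx(expected)

    def test_parity_soundness(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            net, names = random_signed_network(rng)
            if names[0] not in net.graph or names[-1] not in net.graph:
                continue
            got = min_cost_signed_path(net, names[0], names[-1], -1)
            if got is not None:
                assert net_sign(got.edge_signs, "strict") == -1
                assert len(set(got.nodes)) == len(got.nodes)

    def test_cost_monotonicity(self):
        # raising one edge cost never lowers the optimum
        rng = np.random.default_rng(3)
        net, names = random_signed_network(rng)
        base = min_cost_signed_path(net, names[0], names[-1], 1)
        if base is None:
            pytest.skip("no feasible path in this instance")
        u, v = base.nodes[0], base.nodes[1]
        net.graph[u][v]["cost"] += 5.0
        bumped = min_cost_signed_path(net, names[0], names[-1], 1)
        assert bumped is None or bumped.total_cost >= base.total_cost


class TestScoring:
    def test_single_path_score_is_exp_minus_cost(self):
        net = build_net([("R", "X", 1, 1.0), ("X", "TNF", 1, 1.5)])
        score = score_receptor(net, "R", PhenotypeTargets(pro=frozenset({"TNF"})))
        assert score.pro_score == pytest.approx(math.exp(-2.5))
        assert score.anti_score == 0.0

    def test_no_paths_means_zero_composite(self):
        net = build_net([("X", "TNF", 1, 1.0)])
        net.add_node("R")
        score = score_receptor(net, "R")
        assert score.composite == 0.0

    def test_inhibiting_anti_target_counts_pro(self):
        net = build_net([("R", "X", -1, 1.0), ("X", "TGFBR2", 1, 1.0)])
        score = score_receptor(net, "R")
        assert score.pro_score == pytest.approx(math.exp(-2.0))
        assert score.anti_score == 0.0

    def test_pro_vs_anti_receptors_order(self):
        net = build_net(
            [
                ("R1", "A", 1, 1.0), ("A", "TNF", 1, 1.0),
                ("R2", "B", 1, 1.0), ("B", "TGFBR2", 1, 1.0),
            ]
        )
        scores = {s.receptor: s for s in rank_receptors(net, ["R1", "R2"])}
        assert scores["R1"].composite > 0 > scores["R2"].composite
        assert scores["R1"].rank == 1 and scores["R2"].rank == 2


class TestRanking:
    def test_tie_broken_lexicographically(self):
        net = build_net([("B", "TNF", 1, 1.0), ("A", "TNF", 1, 1.0)])
        scores = rank_receptors(net, ["A", "B"])
        assert [s.receptor for s in scores] == ["A", "B"]
        assert [s.rank for s in scores] == [1, 2]

    def test_empty_receptor_set_rejected(self):
        net = build_net([("A", "TNF", 1, 1.0)])
        with pytest.raises(EmptyReceptorSetError):
            rank_receptors(net, [])

    def test_target_receptors_excluded_as_degenerate(self):
        net = build_net([("TGFBR2", "TNF", 1, 1.0), ("R", "TNF", 1, 1.0)])
        scores = rank_receptors(net, ["TGFBR2", "R"])
        assert [s.receptor for s in scores] == ["R"]

    def test_missing_receptor_scores_zero(self):
        net = build_net([("R", "TNF", 1, 1.0)])
        scores = {s.receptor: s for s in rank_receptors(net, ["R", "ABSENT"])}
        assert scores["ABSENT"].composite == 0.0
        assert scores["R"].rank == 1

    def test_deterministic(self):
        net = build_net([("R", "X", 1, 1.0), ("X", "TNF", -1, 1.0), ("R", "TNF", 1, 2.0)])
        a = rank_receptors(net, ["R"])
        b = rank_receptors(net, ["R"])
        assert [(s.receptor, s.rank, s.composite) for s in a] == [
            (s.receptor, s.rank, s.composite) for s in b
        ]


class TestCuratedFixture:
    """The bundled macrophage network reproduces the expected biology."""

    def test_tnf_and_il1_receptors_top_ranked(self):
        net = load_curated_network()
        scores = rank_receptors(net, load_curated_receptors())
        top3 = {s.receptor for s in scores[:3]}
        assert "TNFRSF1A" in top3
        assert "IL1R1" in top3

    def test_composites_match_hand_evaluation(self):
        # hand evaluation of exp(-cost) aggregation over the fixture's
        # cheapest routes (receptor -> NF-kB costs 4, NF-kB -> cytokine
        # costs 1/1.5/1.5/2 by evidence)
        k = math.exp(-1) + 2 * math.exp(-1.5) + math.exp(-2)
        net = load_curated_network()
        scores = {s.receptor: s for s in rank_receptors(net, load_curated_receptors())}
        assert scores["IL1R1"].composite == pytest.approx(math.exp(-4) * k, rel=1e-9)
        assert scores["TNFRSF1A"].composite == pytest.approx(math.exp(-4) * k, rel=1e-9)
        expected_icam1 = math.exp(-5) + 2 * math.exp(-7.5) + math.exp(-8)
        assert scores["ICAM1"].composite == pytest.approx(expected_icam1, rel=1e-9)
        expected_ccr5 = math.exp(-6) * k - math.exp(-3.5)
        assert scores["CCR5"].composite == pytest.approx(expected_ccr5, rel=1e-9)

    def test_double_inhibition_route_activates(self):
        # ICAM1 -| PTEN -| AKT1 -> NF-kB composes to a net activation
        net = load_curated_network()
        path = min_cost_signed_path(net, "ICAM1", "NFKB1", 1)
        assert path is not None
        assert path.net_sign == 1
        assert sum(1 for s in path.edge_signs if s == -1) % 2 == 0


def test_planted_cascade_receptor_recovery_sample():
    """Planted high-evidence cascades win the ranking (small seed sample)."""
    from mevrank.annotation import build_evidence
    from mevrank.deg import run_contrasts
    from mevrank.synthetic import default_study

    wins = 0
    for seed in range(5):
        study = default_study(seed=seed)
        deg = run_contrasts(study.expression)
        evidence = build_evidence(deg.intersection, deg, study.annotations)
        net = assign_costs(study.network, evidence)
        scores = rank_receptors(net, study.receptors)
        wins += scores[0].receptor == "RCPT1"
    assert wins == 5
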