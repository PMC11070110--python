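"""Sign-constrained minimum-cost path search and receptor ranking.

The central question: which plasma-membrane receptors, when engaged,
drive the pro-inflammatory (M1) transcriptional program?  A receptor is
credited for paths that *up*-regulate pro-inflammatory targets (net
path sign +1, the product of edge signs — double inhibition activates)
and for paths that *down*-regulate anti-inflammatory targets (net sign
-1); the mirror combinations count against it.

Minimum-cost sign-consistent paths are found on a parity-layered graph:
each node is split into a (+) and a (-) copy, and an edge u->v with
sign s connects (u, p) to (v, p*s).  Dijkstra on the layered graph with
the strictly positive evidence costs then yields the cheapest walk
whose accumulated sign matches the requirement; when that walk revisits
a base node, an exact bounded-depth enumeration of simple paths takes
over.

Per-path credit is exp(-cost), so short, well-evidenced routes dominate
and unreachable targets contribute exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import (
    EmptyReceptorSetError,
    MissingNodeError,
    ValidationError,
)
from .network import SignalingNetwork

log = logging.getLogger(__name__)

DEFAULT_FALLBACK_DEPTH = 12


@dataclass(frozen=True)
class PhenotypeTargets:
    """Terminal genes whose regulation defines the M1 phenotype.

    ``pro`` genes are up in M1 (inflammatory cytokines); ``anti`` genes
    mark the anti-inflammatory program and are down in M1.
    """

    pro: frozenset[str] = frozenset({"TNF", "IL6", "IL1B", "IL12B"})
    anti: frozenset[str] = frozenset({"TGFBR2", "ADORA3", "FFAR4"})

    def __post_init__(self) -> None:
        if not self.pro:
            raise ValidationError("pro-target set must be non-empty")
        if self.pro & self.anti:
            raise ValidationError("pro and anti target sets must be disjoint")


@dataclass(frozen=True)
class PathResult:
    """A sign-consistent path and its bookkeeping."""

    source: str
    target: str
    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    net_sign: int
    total_cost: float


@dataclass
class ReceptorScore:
    receptor: str
    pro_score: float = 0.0
    anti_score: float = 0.0
    rank: int = 0
    paths: list[PathResult] = field(default_factory=list)

    @property
    def composite(self) -> float:
        return self.pro_score - self.anti_score


def net_sign(edge_signs: Sequence[int], mode: str = "strict") -> int:
    """Compose edge signs along a path.

    Strict mode: plain product, so any unknown (0) sign zeroes the
    path.  Lenient mode: unknown signs are treated as activating (their
    cost penalty has already been paid at the edge level).
    """
    if mode not in ("strict", "lenient"):
        raise ValidationError(f"unknown sign mode {mode!r}")
    if not edge_signs:
        raise ValidationError("empty sign sequence")
    product = 1
    for s in edge_signs:
        if s not in (-1, 0, 1):
            raise ValidationError(f"invalid edge sign {s!r}")
        if s == 0:
            if mode == "strict":
                return 0
            continue  # lenient: 0 acts as +1
        product *= s
    return product


def _layered_graph(network: SignalingNetwork, mode: str) -> nx.DiGraph:
    """Parity-layered copy: node (v, p) means 'reached v with sign p'."""
    layered = nx.DiGraph()
    for u, v, d in sorted(network.graph.edges(data=True)):
        sign = d["sign"]
        if sign == 0:
            if mode == "strict":
                continue  # unusable: would zero the net sign
            sign = 1
        cost = d.get("cost")
        if cost is None:
            raise ValidationError(f"edge {u}->{v} has no cost; run assign_costs first")
        for parity in (1, -1):
            layered.add_edge((u, parity), (v, parity * sign), weight=cost)
    return layered


def _path_result(network: SignalingNetwork, nodes: Sequence[str], mode: str) -> PathResult:
    signs = tuple(network.sign(u, v) for u, v in zip(nodes, nodes[1:]))
    cost = sum(network.cost(u, v) for u, v in zip(nodes, nodes[1:]))
    return PathResult(
        source=nodes[0],
        target=nodes[-1],
        nodes=tuple(nodes),
        edge_signs=signs,
        net_sign=net_sign(signs, mode),
        total_cost=float(cost),
    )


def _enumerate_best(
    network: SignalingNetwork,
    source: str,
    target: str,
    required_sign: int,
    mode: str,
    depth: int,
) -> PathResult | None:
    best: PathResult | None = None
    for nodes in nx.all_simple_paths(network.graph, source, target, cutoff=depth):
        result = _path_result(network, nodes, mode)
        if result.net_sign != required_sign:
            continue
        if best is None or (result.total_cost, result.nodes) < (best.total_cost, best.nodes):
            best = result
    return best


def min_cost_signed_path(
    network: SignalingNetwork,
    source: str,
    target: str,
    required_sign: int,
    mode: str = "strict",
    fallback_depth: int = DEFAULT_FALLBACK_DEPTH,
) -> PathResult | None:
    """Cheapest simple path from source to target with the required net sign.

    Returns ``None`` when no sign-consistent path exists.  The layered
    Dijkstra optimum is exact whenever it is simple in the base graph
    (which, with strictly positive costs, is the usual case); otherwise
    an exhaustive enumeration of simple paths up to ``fallback_depth``
    edges decides.
    """
    if required_sign not in (-1, 1):
        raise ValidationError(f"required_sign must be +1 or -1, got {required_sign!r}")
    for node in (source, target):
        if node not in network:
            raise MissingNodeError(f"node {node!r} not in network")
    if source == target:
        raise ValidationError("source == target; degenerate query is excluded from scoring")
    layered = _layered_graph(network, mode)
    start, goal = (source, 1), (target, required_sign)
    if start not in layered or goal not in layered:
        return None
    try:
        nodes_layered = nx.dijkstra_path(layered, start, goal, weight="weight")
    except nx.NetworkXNoPath:
        return None
    base_nodes = [n for n, _parity in nodes_layered]
    if len(set(base_nodes)) == len(base_nodes):
        return _path_result(network, base_nodes, mode)
    # layered optimum revisits a base node: fall back to exact enumeration
    return _enumerate_best(network, source, target, required_sign, mode, fallback_depth)


def score_receptor(
    network: SignalingNetwork,
    receptor: str,
    targets: PhenotypeTargets | None = None,
    mode: str = "strict",
    fallback_depth: int = DEFAULT_FALLBACK_DEPTH,
) -> ReceptorScore:
    """Score one receptor against the phenotype target panel.

    pro_score  = sum over pro targets of exp(-cost of best activating
                 path) + sum over anti targets of exp(-cost of best
                 inhibiting path);
    anti_score = the mirror (activating anti targets, inhibiting pro
                 targets).  Unreachable targets contribute 0.
    """
    targets = targets or PhenotypeTargets()
    if receptor not in network:
        raise MissingNodeError(f"receptor {receptor!r} not in network")
    score = ReceptorScore(receptor=receptor)
    panel = [(t, "pro") for t in sorted(targets.pro)] + [(t, "anti") for t in sorted(targets.anti)]
    for target, kind in panel:
        if target not in network or target == receptor:
            continue
        for required in (1, -1):
            path = min_cost_signed_path(
                network, receptor, target, required, mode=mode, fallback_depth=fallback_depth
            )
            if path is None:
                continue
            credit = math.exp(-path.total_cost)
            pro_like = (kind == "pro") == (required == 1)
            if pro_like:
                score.pro_score += credit
            else:
                score.anti_score += credit
            score.paths.append(path)
    return score


def rank_receptors(
    network: SignalingNetwork,
    receptor_set: Iterable[str],
    targets: PhenotypeTargets | None = None,
    mode: str = "strict",
    ranking: str = "composite",
    fallback_depth: int = DEFAULT_FALLBACK_DEPTH,
) -> list[ReceptorScore]:
    """Rank candidate receptors by their capacity to drive the M1 program.

    Receptors missing from the network score 0 (logged); receptors that
    are themselves phenotype targets are excluded as degenerate
    (logged).  Sorting is by composite (or pro-only) score descending
    with lexicographic tie-break; ranks are 1..n.
    """
    if ranking not in ("composite", "pro_only"):
        raise ValidationError(f"unknown ranking mode {ranking!r}")
    targets = targets or PhenotypeTargets()
    receptors = sorted(set(receptor_set))
    if not receptors:
        raise EmptyReceptorSetError("no candidate receptors to rank")
    degenerate = [r for r in receptors if r in targets.pro | targets.anti]
    if degenerate:
        log.warning("excluded %d receptor(s) that are phenotype targets: %s",
                    len(degenerate), degenerate)
        receptors = [r for r in receptors if r not in degenerate]
        if not receptors:
            raise EmptyReceptorSetError("all candidate receptors were phenotype targets")
    scores: list[ReceptorScore] = []
    n_missing = 0
    for receptor in receptors:
        if receptor not in network:
            scores.append(ReceptorScore(receptor=receptor))
            n_missing += 1
            continue
        scores.append(
            score_receptor(network, receptor, targets, mode=mode, fallback_depth=fallback_depth)
        )
    if n_missing:
        log.warning("%d candidate receptor(s) absent from network; scored 0", n_missing)
    key = (lambda s: (-s.pro_score, s.receptor)) if ranking == "pro_only" else (
        lambda s: (-s.composite, s.receptor)
    )
    scores.sort(key=key)
    for i, score in enumerate(scores, start=1):
        score.rank = i
    return scores
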