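"""Signed, evidence-costed signaling network.

Nodes are gene/protein symbols; a directed edge u -> v means the
upstream node acts on the downstream one, with a sign: +1 activation
(agonistic), -1 inhibition (antagonistic), 0 unknown.  Curated edges
come from pathway-database-style edge lists; extension edges come from
an interaction candidate list whose signs are inferred from expression
correlation.  Traversal costs are strictly positive and penalise edges
whose downstream node lacks transcript (mRNA) or antibody (mAb)
evidence, and edges of unknown sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientSamplesError,
    MissingNodeError,
    NonPositiveCostError,
    ValidationError,
)
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

SIGN_TOKENS = {"activates": 1, "inhibits": -1, "unknown": 0}
TOKEN_OF_SIGN = {v: k for k, v in SIGN_TOKENS.items()}
VALID_SIGNS = (-1, 0, 1)
PROVENANCES = ("curated", "extension")


@dataclass(frozen=True)
class CostParams:
    """Knobs of the additive edge-cost model.

    cost(u->v) = base_cost
               + lambda_mrna     if v lacks transcript support
               + lambda_mab      if v lacks antibody confirmation
               + lambda_unsigned if the edge sign is unknown

    ``base_cost`` must stay positive so shortest-path search is sound.
    ``correlation_alpha`` / ``min_samples_for_correlation`` govern the
    correlation-based sign inference used for extension edges.
    """

    base_cost: float = 1.0
    lambda_mrna: float = 0.5
    lambda_mab: float = 0.5
    lambda_unsigned: float = 0.5
    correlation_alpha: float = 0.05
    min_samples_for_correlation: int = 4

    def __post_init__(self) -> None:
        if self.base_cost <= 0:
            raise NonPositiveCostError(f"base_cost must be > 0, got {self.base_cost}")
        for name in ("lambda_mrna", "lambda_mab", "lambda_unsigned"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.correlation_alpha < 1:
            raise ValidationError("correlation_alpha must lie in (0, 1)")
        if self.min_samples_for_correlation < 3:
            raise ValidationError("min_samples_for_correlation must be >= 3")


class SignalingNetwork:
    """Thin wrapper over a ``networkx.DiGraph`` with signed, costed edges."""

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction --------------------------------------------------

    def add_edge(self, source: str, target: str, sign: int,
                 provenance: str = "curated", cost: float | None = None) -> None:
        if source == target:
            raise ValidationError(f"self-loop {source}->{target} not allowed")
        if sign not in VALID_SIGNS:
            raise ValidationError(f"invalid sign {sign!r} for {source}->{target}")
        if provenance not in PROVENANCES:
            raise ValidationError(f"invalid provenance {provenance!r}")
        if cost is not None and cost <= 0:
            raise NonPositiveCostError(f"cost of {source}->{target} must be > 0")
        attrs = {"sign": sign, "provenance": provenance}
        if cost is not None:
            attrs["cost"] = float(cost)
        self.graph.add_edge(source, target, **attrs)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(self.graph.copy())

    # -- accessors -----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def sign(self, u: str, v: str) -> int:
        return self.graph[u][v]["sign"]

    def cost(self, u: str, v: str) -> float:
        return self.graph[u][v]["cost"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        """Edge table sorted by (source, target); canonical serial form."""
        rows = [
            {
                "source": u,
                "target": v,
                "sign": d["sign"],
                "provenance": d["provenance"],
                "cost": d.get("cost", np.nan),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["source", "target", "sign", "provenance", "cost"])
        return frame.sort_values(["source", "target"], ignore_index=True)

    def equal_edges(self, other: "SignalingNetwork") -> bool:
        return self.edges_frame().equals(other.edges_frame())


# ---------------------------------------------------------------------------
# merging curated edge lists
# ---------------------------------------------------------------------------

def merge_edge_records(
    records: Iterable[tuple[str, str, int]],
    provenance: str = "curated",
) -> SignalingNetwork:
    """Union edge records into one network.

    Duplicate (source, target) pairs with agreeing signs collapse to a
    single edge; disagreeing duplicates resolve to sign 0 (unknown) and
    are counted.  Self-loops are dropped with a warning.  The result is
    independent of record order.
    """
    signs: dict[tuple[str, str], set[int]] = {}
    dropped_loops = 0
    for source, target, sign in records:
        if sign not in VALID_SIGNS:
            raise ValidationError(f"invalid sign {sign!r} for {source}->{target}")
        if source == target:
            dropped_loops += 1
            continue
        signs.setdefault((source, target), set()).add(sign)
    if dropped_loops:
        log.warning("dropped %d self-loop edge(s)", dropped_loops)
    net = SignalingNetwork()
    conflicts = 0
    for (source, target), sign_set in sorted(signs.items()):
        if len(sign_set) == 1:
            sign = next(iter(sign_set))
        else:
            # conflicting curated signs: neither direction is trustworthy
            sign = 0
            conflicts += 1
        net.add_edge(source, target, sign, provenance=provenance)
    if conflicts:
        log.warning("resolved %d conflicting duplicate sign(s) to unknown", conflicts)
    return net


def load_and_merge(edge_files: Sequence[str]) -> SignalingNetwork:
    """Parse one or more edge-list TSVs and merge them (order-independent)."""
    from . import io as mio  # local import to avoid a cycle

    records: list[tuple[str, str, int]] = []
    for path in edge_files:
        records.extend(
            (r.source, r.target, r.sign) for r in mio.read_edge_list(path)
        )
    return merge_edge_records(records)


# ---------------------------------------------------------------------------
# correlation-based sign inference (network extension)
# ---------------------------------------------------------------------------

def infer_edge_sign(
    expr: ExpressionMatrix,
    gene_u: str,
    gene_v: str,
    params: CostParams | None = None,
) -> int:
    """Infer an interaction sign from co-expression.

    Pearson correlation of the two genes' log2 profiles over all samples;
    a significant positive correlation is read as agonistic (+1), a
    significant negative one as antagonistic (-1), and an insignificant
    correlation as unknown (0).  Significance uses the two-sided
    t-distributed test for r at ``params.correlation_alpha``.
    """
    params = params or CostParams()
    for g in (gene_u, gene_v):
        if g not in expr.genes:
            raise MissingNodeError(f"gene {g!r} absent from expression matrix")
    n = len(expr.samples)
    if n < params.min_samples_for_correlation:
        raise InsufficientSamplesError(
            f"need >= {params.min_samples_for_correlation} samples for correlation, have {n}"
        )
    values = expr.log2_values()
    x = values.loc[gene_u].to_numpy(dtype=float)
    y = values.loc[gene_v].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero-variance gene in (%s, %s); sign set to unknown", gene_u, gene_v)
        return 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    if not np.isfinite(r) or p >= params.correlation_alpha:
        return 0
    return 1 if r > 0 else -1


def extend_with_candidates(
    network: SignalingNetwork,
    candidate_edges: Iterable[tuple[str, str]],
    expr: ExpressionMatrix,
    params: CostParams | None = None,
) -> SignalingNetwork:
    """Add candidate interaction edges with correlation-inferred signs.

    Candidates already present in the curated network are ignored:
    curated evidence always takes precedence over inferred extension.
    Returns a new network; the input is not modified.
    """
    params = params or CostParams()
    out = network.copy()
    added = skipped = 0
    for u, v in sorted(set(candidate_edges)):
        if u == v:
            continue
        if out.has_edge(u, v):
            skipped += 1
            continue
        sign = infer_edge_sign(expr, u, v, params)
        out.add_edge(u, v, sign, provenance="extension")
        added += 1
    log.info("extension: added %d edge(s), skipped %d curated collision(s)", added, skipped)
    return out


# ---------------------------------------------------------------------------
# evidence-based edge costs
# ---------------------------------------------------------------------------

def assign_costs(
    network: SignalingNetwork,
    evidence: pd.DataFrame,
    params: CostParams | None = None,
) -> SignalingNetwork:
    """Attach a positive traversal cost to every edge.

    ``evidence`` is indexed by gene with boolean columns
    ``mrna_supported`` and ``mab_confirmed`` (see
    :func:`mevrank.annotation.build_evidence`).  Nodes absent from the
    table are treated as having no evidence (all-false profile); their
    count is logged.  Activation-vs-inhibition is carried by the edge
    sign, never by the cost.
    """
    params = params or CostParams()
    out = network.copy()
    missing = set()

    def flags(gene: str) -> tuple[bool, bool]:
        if gene in evidence.index:
            row = evidence.loc[gene]
            return bool(row["mrna_supported"]), bool(row["mab_confirmed"])
        missing.add(gene)
        return False, False

    for u, v, d in out.graph.edges(data=True):
        mrna, mab = flags(v)
        cost = params.base_cost
        if not mrna:
            cost += params.lambda_mrna
        if not mab:
            cost += params.lambda_mab
        if d["sign"] == 0:
            cost += params.lambda_unsigned
        d["cost"] = float(cost)
    if missing:
        log.warning("%d node(s) without evidence profile; treated as all-false", len(missing))
    return out
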