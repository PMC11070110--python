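"""Synthetic study generator with planted ground truth.

Emulates a three-condition polarized-macrophage microarray design
(M0 resting, M1 pro-inflammatory, M2 = IL-4-induced M2a; one 24-h
timepoint; three replicates per condition).  Expression is simulated on
the log2 intensity scale: every gene has a common baseline mean, genes
planted as M1-up (or M1-down) have their M1 mean shifted by +effect
(or -effect) log2 units, and i.i.d. Gaussian noise is added per cell.
Network fixtures plant signed receptor->...->target cascades inside a
random background so that the downstream search stages can be scored
against known truth.

The generator defines the study conditions for every downstream test;
its defaults (500 genes, 20 up + 20 down at effect 2.0, noise sd 0.25,
3 replicates) are fixed, not tuning knobs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnknownGeneError, ValidationError
from .expression import CONDITIONS, ExpressionMatrix
from .network import SignalingNetwork

__all__ = [
    "SimulationParams",
    "PlantedCascade",
    "NetworkFixtureParams",
    "SyntheticTruth",
    "default_gene_universe",
    "generate_expression",
    "generate_network",
    "generate_annotations",
    "write_fixture_bundle",
    "StudyFixture",
    "default_study",
]


def default_gene_universe(n_genes: int, named: tuple[str, ...] = ()) -> tuple[str, ...]:
    """Gene universe of ``n_genes`` symbols, optionally starting with real names."""
    if len(named) > n_genes:
        raise ValidationError("more named genes than universe size")
    fillers = tuple(f"G{i:04d}" for i in range(1, n_genes - len(named) + 1))
    return tuple(named) + fillers


@dataclass(frozen=True)
class SimulationParams:
    """Design of the simulated expression study."""

    gene_universe: tuple[str, ...]
    planted_up: frozenset[str] = frozenset()
    planted_down: frozenset[str] = frozenset()
    n_replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    effect_size: float = 2.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ValidationError("gene universe contains duplicates")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.planted_up & self.planted_down:
            raise ValidationError("planted up/down sets must be disjoint")
        universe = set(self.gene_universe)
        for name, genes in (("planted_up", self.planted_up), ("planted_down", self.planted_down)):
            unknown = genes - universe
            if unknown:
                raise UnknownGeneError(f"{name} genes not in universe: {sorted(unknown)[:5]}")
        if "M1" not in self.conditions:
            raise ValidationError("conditions must include M1")

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationParams":
        """The default study: 500 genes, 20 planted up + 20 down."""
        universe = default_gene_universe(500)
        return cls(
            gene_universe=universe,
            planted_up=frozenset(universe[:20]),
            planted_down=frozenset(universe[20:40]),
            seed=seed,
        )


@dataclass(frozen=True)
class PlantedCascade:
    """A signed chain receptor -> intermediates... -> terminal target."""

    receptor: str
    intermediates: tuple[str, ...]
    target: str
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        nodes = self.node_sequence
        if len(set(nodes)) != len(nodes):
            raise ValidationError(f"cascade nodes must be distinct: {nodes}")
        if len(self.signs) != len(nodes) - 1:
            raise ValidationError("need one sign per cascade edge")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValidationError("cascade signs must be +1 or -1")

    @property
    def node_sequence(self) -> tuple[str, ...]:
        return (self.receptor, *self.intermediates, self.target)

    @property
    def edges(self) -> tuple[tuple[str, str, int], ...]:
        nodes = self.node_sequence
        return tuple(
            (nodes[i], nodes[i + 1], self.signs[i]) for i in range(len(nodes) - 1)
        )


@dataclass(frozen=True)
class NetworkFixtureParams:
    """Design of the synthetic network fixture."""

    n_background_nodes: int = 60
    planted_cascades: tuple[PlantedCascade, ...] = ()
    background_edge_density: float = 0.05
    fraction_inhibitory: float = 0.2
    # genes never drawn into the background (e.g. phenotype readout
    # terminals, which only planted cascades may reach)
    excluded_nodes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_edge_density < 1:
            raise ValidationError("background_edge_density must lie in [0, 1)")
        if not 0 <= self.fraction_inhibitory <= 1:
            raise ValidationError("fraction_inhibitory must lie in [0, 1]")
        if self.n_background_nodes < 0:
            raise ValidationError("n_background_nodes must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute the expected outcome of a fixture."""

    planted_up: tuple[str, ...] = ()
    planted_down: tuple[str, ...] = ()
    cascade_receptors: tuple[str, ...] = ()
    cascades: tuple[PlantedCascade, ...] = ()
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "cascade_receptors": sorted(self.cascade_receptors),
            "cascades": [dataclasses.asdict(c) for c in self.cascades],
            "params": self.params,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_up=tuple(d["planted_up"]),
            planted_down=tuple(d["planted_down"]),
            cascade_receptors=tuple(d["cascade_receptors"]),
            cascades=tuple(
                PlantedCascade(
                    receptor=c["receptor"],
                    intermediates=tuple(c["intermediates"]),
                    target=c["target"],
                    signs=tuple(c["signs"]),
                )
                for c in d["cascades"]
            ),
            params=d["params"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_expression(params: SimulationParams) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2-scale expression matrix with planted M1 effects."""
    rng = np.random.default_rng(params.seed)
    genes = list(params.gene_universe)
    sample_ids = [
        f"{cond}_r{i}" for cond in params.conditions for i in range(1, params.n_replicates + 1)
    ]
    conditions = pd.Series(
        [s.split("_")[0] for s in sample_ids], index=sample_ids, name="condition"
    )
    means = np.full((len(genes), len(sample_ids)), params.baseline_log2_mean)
    m1_cols = np.array([c == "M1" for c in conditions])
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in params.planted_up:
        means[gene_pos[g], m1_cols] += params.effect_size
    for g in params.planted_down:
        means[gene_pos[g], m1_cols] -= params.effect_size
    values = means + rng.normal(0.0, params.noise_sd, size=means.shape)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        conditions=conditions,
        scale="log2",
    )
    truth = SyntheticTruth(
        planted_up=tuple(sorted(params.planted_up)),
        planted_down=tuple(sorted(params.planted_down)),
        params=_params_dict(params),
        seed=params.seed,
    )
    return matrix, truth


def generate_network(
    params: NetworkFixtureParams, gene_universe: tuple[str, ...] | list[str]
) -> tuple[SignalingNetwork, SyntheticTruth]:
    """Plant signed cascades inside a random directed background.

    Background edges are drawn Erdos-Renyi-style at the stated density
    over the background nodes plus cascade sources, with three
    exclusions: self-loops, duplicates of planted edges, and edges whose
    *target* is a cascade node.  The last rule keeps each planted
    cascade the unique regulatory route to its terminal, so recovery
    experiments measure the ranking machinery rather than accidental
    background shortcuts (see docs/methods.md).
    """
    rng = np.random.default_rng(params.seed)
    universe = list(gene_universe)
    universe_set = set(universe)
    cascade_nodes: set[str] = set()
    for cascade in params.planted_cascades:
        missing = set(cascade.node_sequence) - universe_set
        if missing:
            raise UnknownGeneError(f"cascade nodes not in universe: {sorted(missing)}")
        cascade_nodes.update(cascade.node_sequence)

    net = SignalingNetwork()
    planted_edges: set[tuple[str, str]] = set()
    for cascade in params.planted_cascades:
        for u, v, s in cascade.edges:
            net.add_edge(u, v, s, provenance="curated")
            planted_edges.add((u, v))

    pool = [g for g in universe if g not in cascade_nodes and g not in params.excluded_nodes]
    if params.n_background_nodes > len(pool):
        raise ValidationError("not enough universe genes for requested background")
    background = sorted(rng.choice(pool, size=params.n_background_nodes, replace=False))
    for node in background:
        net.add_node(node)

    all_nodes = sorted(cascade_nodes | set(background))
    for u in all_nodes:
        for v in background:  # never target a cascade node
            if u == v or (u, v) in planted_edges:
                continue
            if rng.random() < params.background_edge_density:
                sign = -1 if rng.random() < params.fraction_inhibitory else 1
                net.add_edge(u, v, sign, provenance="curated")

    truth = SyntheticTruth(
        cascade_receptors=tuple(sorted(c.receptor for c in params.planted_cascades)),
        cascades=params.planted_cascades,
        params=_params_dict(params),
        seed=params.seed,
    )
    return net, truth


def generate_annotations(
    gene_universe: tuple[str, ...] | list[str],
    receptor_set: set[str] | frozenset[str],
    mab_set: set[str] | frozenset[str] = frozenset(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Annotation table flagging plasma-membrane receptors and mAb hits.

    ``seed`` is accepted for interface symmetry with the other
    generators; the table is deterministic and ignores it.
    """
    universe = list(gene_universe)
    universe_set = set(universe)
    for name, genes in (("receptor_set", set(receptor_set)), ("mab_set", set(mab_set))):
        unknown = genes - universe_set
        if unknown:
            raise UnknownGeneError(f"{name} genes not in universe: {sorted(unknown)[:5]}")
    return pd.DataFrame(
        {
            "pm_localized": [g in receptor_set for g in universe],
            "is_receptor": [g in receptor_set for g in universe],
            "mab_confirmed": [g in mab_set for g in universe],
        },
        index=pd.Index(universe, name="gene"),
    )


def write_fixture_bundle(
    out_dir: str | Path,
    expression: ExpressionMatrix,
    network: SignalingNetwork,
    annotations: pd.DataFrame,
    truth: SyntheticTruth,
    create_missing: bool = True,
) -> dict[str, Path]:
    """Write a full fixture (expression, sheet, edges, annotations, truth).

    Every file round-trips losslessly through the package readers.  With
    ``create_missing`` (the default) the output directory is created;
    otherwise a missing directory raises ``FileNotFoundError``.
    """
    from . import io as mio

    out = Path(out_dir)
    if not out.exists():
        if not create_missing:
            raise FileNotFoundError(f"output directory {out} does not exist")
        out.mkdir(parents=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "edges": out / "edges.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
    }
    mio.write_expression(expression, paths["expression"], paths["samples"])
    mio.write_edge_list(network, paths["edges"])
    mio.write_annotations(annotations, paths["annotations"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# the default simulated study (expression + network + annotations)
# ---------------------------------------------------------------------------

# genes with real symbols so the phenotype-target panel applies unchanged
_NAMED_GENES = (
    "TNF", "IL6", "IL1B", "IL12B", "CCL5", "ICAM1",
    "TGFBR2", "ADORA3", "FFAR4",
    "RCPT1", "KIN1", "KIN2",
)
_PLANTED_UP_NAMED = ("TNF", "IL6", "IL1B", "IL12B", "CCL5", "ICAM1", "RCPT1", "KIN1", "KIN2")
_PLANTED_DOWN_NAMED = ("TGFBR2", "ADORA3", "FFAR4")
_N_DECOY_RECEPTORS = 9


@dataclass
class StudyFixture:
    """One fully simulated study: expression, network, annotations, truth."""

    expression: ExpressionMatrix
    network: SignalingNetwork
    annotations: pd.DataFrame
    truth: SyntheticTruth
    receptors: tuple[str, ...]
    sim_params: SimulationParams
    net_params: NetworkFixtureParams


def default_study(seed: int = 0, noise_sd: float = 0.25) -> StudyFixture:
    """Simulate the default end-to-end study.

    500 genes (20 planted up, 20 down, effect 2.0), one fully evidenced
    cascade RCPT1 -> KIN1 -> KIN2 -> TNF (all activating) inside a
    60-node background at density 0.05, and annotations marking the
    planted receptor plus nine background decoy receptors as
    plasma-membrane receptors, with mAb confirmation on the cascade.
    """
    universe = default_gene_universe(500, named=_NAMED_GENES)
    filler = [g for g in universe if g.startswith("G")]
    planted_up = frozenset(_PLANTED_UP_NAMED) | frozenset(filler[:20 - len(_PLANTED_UP_NAMED)])
    planted_down = frozenset(_PLANTED_DOWN_NAMED) | frozenset(
        filler[20:40 - len(_PLANTED_DOWN_NAMED)]
    )
    sim_params = SimulationParams(
        gene_universe=universe,
        planted_up=planted_up,
        planted_down=planted_down,
        noise_sd=noise_sd,
        seed=seed,
    )
    expression, expr_truth = generate_expression(sim_params)

    cascade = PlantedCascade(
        receptor="RCPT1", intermediates=("KIN1", "KIN2"), target="TNF", signs=(1, 1, 1)
    )
    panel = ("TNF", "IL6", "IL1B", "IL12B", "TGFBR2", "ADORA3", "FFAR4")
    net_params = NetworkFixtureParams(
        n_background_nodes=60,
        planted_cascades=(cascade,),
        background_edge_density=0.05,
        fraction_inhibitory=0.2,
        excluded_nodes=panel,
        seed=seed + 1,
    )
    network, net_truth = generate_network(net_params, universe)

    planted = planted_up | planted_down
    background = sorted(
        n for n in network.graph.nodes
        if n not in cascade.node_sequence and n not in planted
    )
    decoys = tuple(background[:_N_DECOY_RECEPTORS])
    receptors = ("RCPT1",) + decoys
    annotations = generate_annotations(
        universe,
        receptor_set=set(receptors),
        mab_set={"RCPT1", "KIN1", "KIN2", "TNF", "ICAM1"},
    )
    truth = SyntheticTruth(
        planted_up=expr_truth.planted_up,
        planted_down=expr_truth.planted_down,
        cascade_receptors=net_truth.cascade_receptors,
        cascades=net_truth.cascades,
        params={"simulation": expr_truth.params, "network": net_truth.params},
        seed=seed,
    )
    return StudyFixture(
        expression=expression,
        network=network,
        annotations=annotations,
        truth=truth,
        receptors=receptors,
        sim_params=sim_params,
        net_params=net_params,
    )


def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    out = {}
    for key, value in d.items():
        if isinstance(value, frozenset):
            out[key] = sorted(value)
        elif key == "planted_cascades":
            out[key] = value  # list of dicts from asdict
        else:
            out[key] = value
    return out
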