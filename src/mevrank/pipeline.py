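"""End-to-end orchestration of the receptor-ranking pipeline.

Stage order: read inputs -> differential expression (two contrasts,
BH-FDR, intersection) -> plasma-membrane receptor filter -> evidence
profiles -> network merge / extension / cost assignment -> ranking.
Every run emits the DEG table, the costed network, the evidence table,
the ranking TSV, a JSON report (config echo, input checksums, stage
timings and counts, warnings, final ranking) and a log file.  Reruns on
identical inputs produce byte-identical ranking output.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as mio
from .annotation import build_evidence, filter_pm_receptors
from .config import PipelineConfig
from .deg import run_contrasts
from .errors import MevrankError, PipelineError
from .network import assign_costs, extend_with_candidates, load_and_merge
from .ranking import rank_receptors

log = logging.getLogger(__name__)


@dataclass
class RunState:
    """Mutable bookkeeping collected while the pipeline executes."""

    config: PipelineConfig
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    ranking: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None


class _WarningCollector(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record.getMessage())


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunState:
    """Execute all stages; raises :class:`PipelineError` on failure.

    The JSON report is written even when a stage fails, recording the
    failing stage's name.
    """
    state = RunState(config=config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = logging.getLogger("mevrank")
    collector = _WarningCollector(state.warnings)
    file_handler = logging.FileHandler(out / "pipeline.log", mode="w", encoding="utf-8")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(collector)
    root.addHandler(file_handler)
    try:
        _run_stages(config, state, out)
    except Exception as exc:  # report is written for failures too
        if state.failed_stage is None:
            state.failed_stage = "unknown"
        state.error = str(exc)
        _write_report(state, out)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(state.failed_stage, str(exc)) from exc
    finally:
        root.removeHandler(collector)
        root.removeHandler(file_handler)
        file_handler.close()
    _write_report(state, out)
    return state


def _run_stages(config: PipelineConfig, state: RunState, out: Path) -> None:
    def stage(name: str):
        state.failed_stage = name  # cleared on success

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc_type is None:
                    state.stages.append(
                        {"name": name, "seconds": time.perf_counter() - self.t0}
                    )
                    state.failed_stage = None
                return False

        return _Timer()

    with stage("read_inputs"):
        for label, path in [
            ("expression", config.expression),
            ("sample_sheet", config.sample_sheet),
            ("annotations", config.annotations),
            *[(f"curated_edges[{i}]", p) for i, p in enumerate(config.curated_edges)],
        ]:
            if not Path(path).exists():
                raise MevrankError(f"input file missing: {label} = {path}")
            state.checksums[label] = _sha256(Path(path))
        expr = mio.read_expression(config.expression, config.sample_sheet)
        annotations = mio.read_annotations(config.annotations)
        if config.mab_genes is not None:
            state.checksums["mab_genes"] = _sha256(Path(config.mab_genes))
            for gene in mio.read_gene_list(config.mab_genes):
                if gene in annotations.index:
                    annotations.loc[gene, "mab_confirmed"] = True
        state.counts["genes"] = len(expr.genes)
        state.counts["samples"] = len(expr.samples)

    with stage("differential_expression"):
        deg = run_contrasts(
            expr, alpha=config.alpha, direction_concordance=config.direction_concordance
        )
        mio.write_deg_tables(deg, out / "deg_tables.tsv")
        state.counts["deg_intersection"] = len(deg.intersection)
        for contrast in deg.tables:
            state.counts[f"significant_{contrast}"] = len(deg.significant(contrast))

    with stage("membrane_filter"):
        candidates = filter_pm_receptors(sorted(deg.intersection), annotations)
        state.counts["candidate_receptors"] = len(candidates)

    with stage("evidence"):
        evidence = build_evidence(deg.intersection, deg, annotations)
        mio.write_evidence(evidence, out / "evidence.tsv")
        state.counts["evidence_profiles"] = len(evidence)

    with stage("network_build"):
        network = load_and_merge(config.curated_edges)
        if config.candidate_edges is not None:
            state.checksums["candidate_edges"] = _sha256(Path(config.candidate_edges))
            candidate_records = mio.read_edge_list(config.candidate_edges)
            network = extend_with_candidates(
                network,
                [(r.source, r.target) for r in candidate_records],
                expr,
                config.cost_params,
            )
        network = assign_costs(network, evidence, config.cost_params)
        mio.write_edge_list(network, out / "network_edges.tsv")
        state.counts["network_nodes"] = network.n_nodes
        state.counts["network_edges"] = network.n_edges

    with stage("ranking"):
        if not candidates:
            log.warning("no candidate receptors; emitting empty ranking")
            scores = []
        else:
            scores = rank_receptors(
                network,
                candidates,
                config.targets,
                mode=config.sign_mode,
                ranking=config.ranking_mode,
            )
        mio.write_ranking(scores, out / "ranking.tsv")
        state.ranking = mio.ranking_report(scores)
        state.counts["ranked_receptors"] = len(scores)


def _write_report(state: RunState, out: Path) -> None:
    report = {
        "mevrank_version": __version__,
        "config": state.config.to_dict(),
        "seed": state.config.seed,
        "input_checksums": state.checksums,
        "stages": state.stages,
        "counts": state.counts,
        "warnings": state.warnings,
        "ranking": state.ranking,
        "failed_stage": state.failed_stage,
        "error": state.error,
    }
    mio.write_json(report, out / "report.json")
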