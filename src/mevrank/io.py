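"""Readers and writers for the pipeline's on-disk formats.

Everything is UTF-8 TSV with optional ``#`` comment lines:

* expression TSV — first column ``gene``, remaining columns sample ids;
* sample sheet TSV — ``sample_id  condition  timepoint`` plus a
  ``# scale=log2|linear`` metadata comment (the timepoint column is
  carried for format fidelity and ignored by analysis);
* edge list TSV — ``source  relation  target  provenance`` with
  relation tokens activates/inhibits/unknown (SIF-like dialect);
* annotation / evidence TSVs — booleans as ``true``/``false`` tokens;
* ranking TSV — ``receptor  pro_score  anti_score  composite  rank``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ANNOTATION_COLUMNS, EVIDENCE_COLUMNS
from .deg import DegResult
from .errors import ParseError
from .expression import CONDITIONS, ExpressionMatrix
from .network import SIGN_TOKENS, TOKEN_OF_SIGN, PROVENANCES, SignalingNetwork
from .ranking import ReceptorScore

_BOOL_TOKENS = {"true": True, "false": False}

FLOAT_FORMAT = "%.17g"  # full round-trip precision for doubles


def _fmt(x: float) -> str:
    return FLOAT_FORMAT % x


# ---------------------------------------------------------------------------
# expression + sample sheet
# ---------------------------------------------------------------------------

def read_expression(expr_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Load and validate an expression matrix and its sample sheet."""
    expr_path, sample_sheet_path = Path(expr_path), Path(sample_sheet_path)
    scale = "log2"
    rows: list[dict] = []
    with open(sample_sheet_path, encoding="utf-8") as handle:
        header: list[str] | None = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("scale="):
                    scale = body.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["sample_id", "condition"]:
                    raise ParseError(
                        "sample sheet must start with columns sample_id, condition",
                        str(sample_sheet_path), lineno,
                    )
                continue
            rows.append(dict(zip(header, fields)))
    if not rows:
        raise ParseError("empty sample sheet", str(sample_sheet_path))
    sheet = pd.DataFrame(rows).set_index("sample_id")
    unknown = set(sheet["condition"]) - set(CONDITIONS)
    if unknown:
        raise ParseError(
            f"unknown condition label(s) {sorted(unknown)}", str(sample_sheet_path)
        )

    try:
        values = pd.read_csv(
            expr_path, sep="\t", comment="#", index_col="gene",
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise ParseError(f"bad expression header: {exc}", str(expr_path)) from exc
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene row(s): {dup[:5]}", str(expr_path))
    bad = values.columns[~values.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ParseError(f"non-numeric cells in column(s) {list(bad)[:5]}", str(expr_path))
    missing = set(values.columns) - set(sheet.index)
    if missing:
        raise ParseError(
            f"matrix column(s) absent from sample sheet: {sorted(missing)[:5]}",
            str(expr_path),
        )
    conditions = sheet["condition"].reindex(values.columns)
    return ExpressionMatrix(values=values, conditions=conditions, scale=scale)


def write_expression(
    expr: ExpressionMatrix, expr_path: str | Path, sample_sheet_path: str | Path,
    timepoint: str = "24h",
) -> None:
    frame = expr.values.copy()
    frame.index.name = "gene"
    frame.to_csv(expr_path, sep="\t", float_format=FLOAT_FORMAT)
    with open(sample_sheet_path, "w", encoding="utf-8") as handle:
        handle.write(f"# scale={expr.scale}\n")
        handle.write("sample_id\tcondition\ttimepoint\n")
        for sample, condition in expr.conditions.items():
            handle.write(f"{sample}\t{condition}\t{timepoint}\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    sign: int
    provenance: str = "curated"


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    path = Path(path)
    records: list[EdgeRecord] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "source":  # optional header
                continue
            if len(fields) < 3:
                raise ParseError("edge line needs source, relation, target", str(path), lineno)
            source, relation, target = fields[0], fields[1], fields[2]
            if relation not in SIGN_TOKENS:
                raise ParseError(
                    f"unknown relation token {relation!r} "
                    f"(expected one of {sorted(SIGN_TOKENS)})",
                    str(path), lineno,
                )
            provenance = fields[3] if len(fields) > 3 and fields[3] else "curated"
            if provenance not in PROVENANCES:
                raise ParseError(f"unknown provenance {provenance!r}", str(path), lineno)
            records.append(EdgeRecord(source, target, SIGN_TOKENS[relation], provenance))
    return records


def write_edge_list(network: SignalingNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("source\trelation\ttarget\tprovenance\n")
        frame = network.edges_frame()
        for row in frame.itertuples(index=False):
            handle.write(
                f"{row.source}\t{TOKEN_OF_SIGN[row.sign]}\t{row.target}\t{row.provenance}\n"
            )


def network_from_records(records: Sequence[EdgeRecord]) -> SignalingNetwork:
    """Build a network verbatim from records (no merge semantics)."""
    net = SignalingNetwork()
    for r in records:
        net.add_edge(r.source, r.target, r.sign, provenance=r.provenance)
    return net


# ---------------------------------------------------------------------------
# boolean tables (annotations, evidence)
# ---------------------------------------------------------------------------

def _read_bool_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="gene", dtype=str)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing}", str(path))
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene row(s): {dup[:5]}", str(path))
    out = {}
    for col in columns:
        if col == "mrna_direction":
            bad = set(frame[col]) - {"up", "down", "none"}
            if bad:
                raise ParseError(f"bad direction token(s) {sorted(bad)}", str(path))
            out[col] = frame[col]
        else:
            bad = set(frame[col].str.lower()) - set(_BOOL_TOKENS)
            if bad:
                raise ParseError(f"bad boolean token(s) {sorted(bad)} in {col}", str(path))
            out[col] = frame[col].str.lower().map(_BOOL_TOKENS)
    return pd.DataFrame(out, index=frame.index)


def _write_bool_table(frame: pd.DataFrame, path: str | Path, columns: tuple[str, ...]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\t" + "\t".join(columns) + "\n")
        for gene, row in frame.sort_index().iterrows():
            cells = [
                str(row[c]) if c == "mrna_direction" else ("true" if row[c] else "false")
                for c in columns
            ]
            handle.write(f"{gene}\t" + "\t".join(cells) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return _read_bool_table(path, ANNOTATION_COLUMNS)


def write_annotations(frame: pd.DataFrame, path: str | Path) -> None:
    _write_bool_table(frame, path, ANNOTATION_COLUMNS)


def read_evidence(path: str | Path) -> pd.DataFrame:
    return _read_bool_table(path, EVIDENCE_COLUMNS)


def write_evidence(frame: pd.DataFrame, path: str | Path) -> None:
    _write_bool_table(frame, path, EVIDENCE_COLUMNS)


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


# ---------------------------------------------------------------------------
# DEG tables, rankings, reports
# ---------------------------------------------------------------------------

def write_deg_tables(result: DegResult, path: str | Path) -> None:
    frame = result.combined_frame()
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\tcontrast\tlogFC\tt\tp_raw\tp_adj\tsignificant\n")
        for row in frame.itertuples(index=False):
            handle.write(
                f"{row.gene}\t{row.contrast}\t{_fmt(row.logFC)}\t{_fmt(row.t)}\t"
                f"{_fmt(row.p_raw)}\t{_fmt(row.p_adj)}\t"
                f"{'true' if row.significant else 'false'}\n"
            )


def write_ranking(scores: Sequence[ReceptorScore], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("receptor\tpro_score\tanti_score\tcomposite\trank\n")
        for s in scores:
            handle.write(
                f"{s.receptor}\t{_fmt(s.pro_score)}\t{_fmt(s.anti_score)}\t"
                f"{_fmt(s.composite)}\t{s.rank}\n"
            )


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ranking_report(scores: Sequence[ReceptorScore]) -> list[dict]:
    """JSON-ready ranking including contributing path node sequences."""
    return [
        {
            "receptor": s.receptor,
            "rank": s.rank,
            "pro_score": s.pro_score,
            "anti_score": s.anti_score,
            "composite": s.composite,
            "paths": [
                {
                    "target": p.target,
                    "nodes": list(p.nodes),
                    "edge_signs": list(p.edge_signs),
                    "net_sign": p.net_sign,
                    "total_cost": p.total_cost,
                }
                for p in s.paths
            ],
        }
        for s in scores
    ]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
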