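"""Plasma-membrane receptor filtering and node evidence profiles.

The annotation table stands in for a UniProt-style query (localization
"cell membrane", function "receptor") plus a monoclonal-antibody
confirmation list.  Evidence profiles combine that table with the
differential-expression result: a node is transcript-supported when it
sits in the two-contrast DEG intersection, and its direction is the
sign of its M2-vs-M1 fold change (the contrast that pits the M1
phenotype against M2).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .deg import DegResult
from .errors import UnknownGeneError, ValidationError

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("pm_localized", "is_receptor", "mab_confirmed")
EVIDENCE_COLUMNS = ("mrna_supported", "mrna_direction", "mab_confirmed")


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    if annotations.index.has_duplicates:
        raise ValidationError("annotation table has duplicate gene rows")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    return annotations


def filter_pm_receptors(genes: Iterable[str], annotations: pd.DataFrame) -> set[str]:
    """Genes that are both plasma-membrane localized and receptors.

    Genes absent from the annotation table carry no localization
    evidence and are excluded; their count is logged.
    """
    validate_annotations(annotations)
    genes = list(genes)
    unannotated = [g for g in genes if g not in annotations.index]
    if unannotated:
        log.warning("%d queried gene(s) missing from annotations; excluded", len(unannotated))
    kept = {
        g
        for g in genes
        if g in annotations.index
        and bool(annotations.at[g, "pm_localized"])
        and bool(annotations.at[g, "is_receptor"])
    }
    return kept


def build_evidence(
    deg_intersection: Iterable[str],
    deg_tables: Mapping[str, pd.DataFrame] | DegResult,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene evidence profile over the full gene universe.

    The universe is the union of DEG-table genes and annotated genes.
    ``mrna_supported`` marks membership in the DEG intersection;
    ``mrna_direction`` ("up"/"down"/"none") is the sign of the
    M2_vs_M1 logFC for supported genes; ``mab_confirmed`` is copied
    from the annotation table (false when unannotated).
    """
    validate_annotations(annotations)
    if isinstance(deg_tables, DegResult):
        deg_tables = deg_tables.tables
    intersection = set(deg_intersection)
    m2_table = deg_tables["M2_vs_M1"]
    missing = intersection - set(m2_table.index)
    if missing:
        raise UnknownGeneError(
            f"intersection gene(s) absent from DEG table: {sorted(missing)[:5]}"
        )
    universe = sorted(set(m2_table.index) | set(annotations.index))

    def direction(gene: str) -> str:
        if gene not in intersection:
            return "none"
        # supported genes always carry a direction; an exactly-zero
        # fold change cannot occur for a significant gene in practice
        # and resolves to "up" to keep direction<->support consistent
        return "up" if m2_table.at[gene, "logFC"] >= 0 else "down"

    return pd.DataFrame(
        {
            "mrna_supported": [g in intersection for g in universe],
            "mrna_direction": [direction(g) for g in universe],
            "mab_confirmed": [
                bool(annotations.at[g, "mab_confirmed"]) if g in annotations.index else False
                for g in universe
            ],
        },
        index=pd.Index(universe, name="gene"),
    )
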