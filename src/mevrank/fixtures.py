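"""Bundled curated macrophage-signaling fixture.

A small, fully signed network distilled from the canonical
pro-inflammatory wiring of macrophages: TNF receptor 1 signaling via
TRADD into NF-kB; IL-1 receptor and TLR1/2 signaling via TIRAP/MyD88
into NF-kB; NF-kB transactivating the M1 cytokines TNF, IL6, IL1B and
IL12B; ICAM1 engaging integrin/MAPK toward TNF and relieving PTEN's
brake on AKT; and CCL5 engaging CCR3/CCR5 with a PI3K/AKT
pro-inflammatory arm and a CCR5/STAT3 arm toward the anti-inflammatory
marker TGFBR2.  Evidence flags reflect the M1 transcript hits (TNF,
IL6, IL1B, CCL5, ICAM1 up; TGFBR2, ADORA3, FFAR4, CD36, MRC1, CD9
down) and antibody-confirmed proteins (TNF, ICAM1).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as mio
from .network import CostParams, SignalingNetwork, assign_costs, load_and_merge
from .ranking import PhenotypeTargets

_DATA = resources.files("mevrank.data")


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(_DATA / name))


def load_curated_network(cost_params: CostParams | None = None) -> SignalingNetwork:
    """The curated fixture network with evidence costs assigned."""
    net = load_and_merge([data_path("curated_edges.tsv")])
    evidence = load_curated_evidence()
    return assign_costs(net, evidence, cost_params or CostParams())


def load_curated_evidence() -> pd.DataFrame:
    return mio.read_evidence(data_path("curated_evidence.tsv"))


def load_curated_annotations() -> pd.DataFrame:
    return mio.read_annotations(data_path("curated_annotations.tsv"))


def load_curated_receptors() -> list[str]:
    return mio.read_gene_list(data_path("curated_receptors.txt"))


def default_targets() -> PhenotypeTargets:
    return PhenotypeTargets()
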