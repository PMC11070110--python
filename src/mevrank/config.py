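"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ValidationError
from .network import CostParams
from .ranking import PhenotypeTargets


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Paths are resolved relative to the config file's directory when
    loaded from YAML.
    """

    expression: Path
    sample_sheet: Path
    curated_edges: tuple[Path, ...]
    annotations: Path
    output_dir: Path
    candidate_edges: Path | None = None
    mab_genes: Path | None = None
    alpha: float = 0.05
    direction_concordance: bool = True
    cost_params: CostParams = field(default_factory=CostParams)
    targets: PhenotypeTargets = field(default_factory=PhenotypeTargets)
    sign_mode: str = "strict"
    ranking_mode: str = "composite"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sign_mode not in ("strict", "lenient"):
            raise ValidationError(f"unknown sign_mode {self.sign_mode!r}")
        if self.ranking_mode not in ("composite", "pro_only"):
            raise ValidationError(f"unknown ranking_mode {self.ranking_mode!r}")
        if not self.curated_edges:
            raise ValidationError("at least one curated edge file is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p is not None else None

        cost = CostParams(**raw.get("cost_params", {}))
        targets_raw = raw.get("targets", {})
        targets = PhenotypeTargets(
            pro=frozenset(targets_raw.get("pro", PhenotypeTargets().pro)),
            anti=frozenset(targets_raw.get("anti", PhenotypeTargets().anti)),
        )
        cfg = cls(
            expression=resolve(raw["expression"]),
            sample_sheet=resolve(raw["sample_sheet"]),
            curated_edges=tuple(resolve(p) for p in raw["curated_edges"]),
            annotations=resolve(raw["annotations"]),
            output_dir=resolve(raw.get("output_dir", "out")),
            candidate_edges=resolve(raw.get("candidate_edges")),
            mab_genes=resolve(raw.get("mab_genes")),
            alpha=float(raw.get("alpha", 0.05)),
            direction_concordance=bool(raw.get("direction_concordance", True)),
            cost_params=cost,
            targets=targets,
            sign_mode=raw.get("sign_mode", "strict"),
            ranking_mode=raw.get("ranking_mode", "composite"),
            seed=int(raw.get("seed", 0)),
        )
        return replace(cfg, **overrides) if overrides else cfg

    def to_dict(self) -> dict:
        return {
            "expression": str(self.expression),
            "sample_sheet": str(self.sample_sheet),
            "curated_edges": [str(p) for p in self.curated_edges],
            "annotations": str(self.annotations),
            "candidate_edges": str(self.candidate_edges) if self.candidate_edges else None,
            "mab_genes": str(self.mab_genes) if self.mab_genes else None,
            "output_dir": str(self.output_dir),
            "alpha": self.alpha,
            "direction_concordance": self.direction_concordance,
            "cost_params": {
                "base_cost": self.cost_params.base_cost,
                "lambda_mrna": self.cost_params.lambda_mrna,
                "lambda_mab": self.cost_params.lambda_mab,
                "lambda_unsigned": self.cost_params.lambda_unsigned,
                "correlation_alpha": self.cost_params.correlation_alpha,
                "min_samples_for_correlation": self.cost_params.min_samples_for_correlation,
            },
            "targets": {"pro": sorted(self.targets.pro), "anti": sorted(self.targets.anti)},
            "sign_mode": self.sign_mode,
            "ranking_mode": self.ranking_mode,
            "seed": self.seed,
        }


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
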