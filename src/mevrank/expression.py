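"""Gene x sample expression container.

The matrix holds microarray-style intensities for polarized macrophage
samples labelled M0 (resting), M1 (pro-inflammatory) and M2
(anti-inflammatory, the IL-4-induced M2a state).  Values live either on
the linear intensity scale or on log2; conversion helpers keep the
differential-expression and correlation code scale-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingConditionError, ValidationError

CONDITIONS = ("M0", "M1", "M2")


@dataclass
class ExpressionMatrix:
    """Expression values (genes x samples) plus per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample ids as columns.
    conditions
        Series mapping each sample id to its condition label.
    scale
        ``"log2"`` or ``"linear"``; the scale ``values`` is stored on.
    """

    values: pd.DataFrame
    conditions: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()].tolist()
            raise ValidationError(f"samples without condition label: {missing[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValidationError("linear-scale intensities must be non-negative")
        counts = self.conditions.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"every condition needs >= 2 samples; offending: {dict(small)}"
            )

    # -- accessors -----------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, condition: str) -> list[str]:
        sel = self.conditions.index[self.conditions == condition].tolist()
        if not sel:
            raise MissingConditionError(
                f"condition {condition!r} not present (have {sorted(self.conditions.unique())})"
            )
        return sel

    def condition_values(self, condition: str, scale: str | None = None) -> pd.DataFrame:
        """Sub-matrix for one condition, optionally converted to ``scale``."""
        sub = self.values[self.samples_for(condition)]
        return self._convert(sub, scale or self.scale)

    def linear_values(self) -> pd.DataFrame:
        return self._convert(self.values, "linear")

    def log2_values(self) -> pd.DataFrame:
        return self._convert(self.values, "log2")

    def _convert(self, frame: pd.DataFrame, scale: str) -> pd.DataFrame:
        if scale == self.scale:
            return frame
        if scale == "linear":
            return np.exp2(frame)
        return np.log2(frame)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and self.conditions.equals(other.conditions)
        )
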