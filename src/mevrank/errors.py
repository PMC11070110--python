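"""Exception hierarchy.

Every rejection the pipeline promises ("named error") maps onto one of
these classes so callers can catch a specific failure mode instead of a
bare ``ValueError``.
"""

from __future__ import annotations


class MevrankError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MevrankError):
    """A parameter object or in-memory table violates its invariants."""


class UnknownGeneError(ValidationError):
    """A gene symbol is referenced that is not in the gene universe."""


class MissingConditionError(MevrankError):
    """A contrast refers to a condition label absent from the matrix."""


class InsufficientSamplesError(MevrankError):
    """A statistical operation received fewer samples than it requires."""


class ParseError(MevrankError):
    """A file failed to parse; carries file path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class MissingNodeError(MevrankError):
    """A path query referenced a node absent from the network."""


class NonPositiveCostError(ValidationError):
    """Edge-cost parameters would allow a non-positive traversal cost."""


class EmptyReceptorSetError(MevrankError):
    """Ranking was requested over an empty candidate receptor set."""


class PipelineError(MevrankError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage
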