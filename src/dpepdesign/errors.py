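"""Exception hierarchy for the design pipeline.

Every stage raises a subclass of :class:`DesignError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class DesignError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(DesignError):
    """A structure file could not be read or violates a parsing precondition."""


class InsertionCodeError(StructureParseError):
    """Input contains residue insertion codes, which are not supported."""


class SegmentGapError(DesignError):
    """A requested residue range is not contiguous in the chain."""

    def __init__(self, chain_id: str, missing: list[int]):
        self.chain_id = chain_id
        self.missing = list(missing)
        super().__init__(
            f"chain {chain_id!r} is missing residue(s) {self.missing} in the requested range"
        )


class HotspotValidationError(DesignError):
    """A hotspot specification does not match the scaffold segment."""


class SchemeError(DesignError):
    """An atom-level scheme names atoms absent from the scaffold, or a
    combination falls below the minimum atom count."""


class DegenerateGeometryError(DesignError):
    """Superposition is ill-posed: fewer than 3 points or (near-)collinear sets."""


class NoMatchesError(DesignError):
    """A search scored zero windows; carries the per-reason skip histogram."""

    def __init__(self, skip_histogram: dict[str, int]):
        self.skip_histogram = dict(skip_histogram)
        super().__init__(f"no scoreable windows (skips by reason: {self.skip_histogram})")


class CoverageError(DesignError):
    """A placed fragment does not cover its assigned scaffold range."""


class ConfigError(DesignError):
    """Pipeline configuration is invalid or references missing files."""


class PipelineStageError(DesignError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
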