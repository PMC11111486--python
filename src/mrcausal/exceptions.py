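"""Typed errors raised across the MR pipeline.

Every contract violation surfaces as a subclass of :class:`MRError` so callers
can catch pipeline failures distinctly from programming errors.
"""

from __future__ import annotations


class MRError(Exception):
    """Base class for all mrcausal errors."""


class MRDataError(MRError, ValueError):
    """Malformed or insufficient input data."""


class MissingColumnError(MRDataError):
    """A required field has no source column in a summary-statistics file."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column {column!r} not found in input")


class EmptyTableError(MRDataError):
    """A summary-statistics table contains zero valid rows."""


class NoOverlapError(MRDataError):
    """Exposure and outcome tables share no variant IDs."""


class UnknownVariantInLDError(MRDataError):
    """Strict-mode clumping met a variant absent from the LD matrix."""

    def __init__(self, variant_id: str):
        self.variant_id = variant_id
        super().__init__(f"variant {variant_id!r} missing from LD matrix")


class MissingFieldError(MRDataError):
    """An operation needs a field (eaf, n, chromosome, position) that is absent."""


class EmptySelectionError(MRDataError):
    """Instrument selection left zero variants; records the emptying stage."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"no instruments survive selection stage {stage!r}")


class TooFewInstrumentsError(MRDataError):
    """An estimator received fewer instruments than its minimum."""

    def __init__(self, method: str, k: int, minimum: int):
        self.method = method
        self.k = k
        self.minimum = minimum
        super().__init__(f"{method} needs at least {minimum} instruments, got {k}")


class CollinearDesignError(MRDataError):
    """Egger regression is undefined when all exposure effects coincide."""


class ZeroExposureEffectError(MRDataError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class InvalidConfigError(MRError, ValueError):
    """A configuration object violates its invariants."""
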