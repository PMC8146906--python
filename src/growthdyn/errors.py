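"""Exception hierarchy.

Every validation failure carries a machine-readable ``reason`` dict so that
callers (and the CLI) can report precisely which invariant was violated.
"""

from __future__ import annotations


class GrowthDynError(Exception):
    """Base class for all package errors."""

    def __init__(self, message: str, reason: dict | None = None):
        super().__init__(message)
        self.reason = reason or {}


class ValidationError(GrowthDynError):
    """A table or config violated a structural invariant."""


class DuplicateKeyError(ValidationError):
    """Duplicate (genotype, treatment, replicate, dat, trait) key."""


class MissingColumnError(ValidationError):
    """A declared column is absent from the input file."""


class UnknownTraitError(GrowthDynError):
    """Requested trait not present in the table."""


class GridError(GrowthDynError):
    """A day is off the declared imaging-day grid, or grids disagree."""


class UndefinedScoreError(GrowthDynError):
    """A capability ratio is undefined (non-positive control increment)."""


class ConvergenceError(GrowthDynError):
    """An iterative fit failed to converge."""
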