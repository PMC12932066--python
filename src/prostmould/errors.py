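"""Exception hierarchy for the mould-generation pipeline.

Every stage raises a subclass of :class:`ProstMouldError` so callers (and the
CLI) can distinguish bad input data from geometric/layout failures.
"""

from __future__ import annotations


class ProstMouldError(Exception):
    """Base class for all package errors."""


class MeshFormatError(ProstMouldError):
    """A file could not be parsed as STL."""


class MeshValidationError(ProstMouldError):
    """A mesh violates the invariants required downstream (watertightness,
    finite coordinates, minimum size).  Carries the :class:`MeshReport`
    describing the defects."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class PhantomSpecError(ProstMouldError):
    """A synthetic-case specification is geometrically infeasible."""


class BooleanError(ProstMouldError):
    """A CSG operation produced unusable (non-watertight) geometry."""


class CalibrationError(ProstMouldError):
    """A guide cannot satisfy the fixed-insertion-depth identity.

    ``deficit_mm`` is how far the target lies beyond the reachable depth.
    """

    def __init__(self, message: str, deficit_mm: float | None = None):
        super().__init__(message)
        self.deficit_mm = deficit_mm


class LayoutError(ProstMouldError):
    """Guide channels collide with each other or with the insertion opening."""
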