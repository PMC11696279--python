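"""Exception hierarchy for rugometry.

All package errors derive from :class:`RugometryError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
(bad input, degenerate geometry, a reference line missing a ruga, a constant
descriptor vector, an empty summary cell, a degenerate rank test, or an
unusable synthetic-palate parameterization).
"""


class RugometryError(Exception):
    """Base class for all rugometry errors."""


class InvalidInputError(RugometryError, ValueError):
    """Input violates a documented precondition (non-finite coordinates, ...)."""


class DegenerateGeometryError(RugometryError, ValueError):
    """Geometry collapses below the tolerance where a quantity is defined."""


class NoIntersectionError(RugometryError, ValueError):
    """A reference line does not cross the ruga polyline it should cross."""

    def __init__(self, message: str, line_label: str | None = None,
                 ruga_index: int | None = None, landmark_index: int | None = None):
        super().__init__(message)
        self.line_label = line_label
        self.ruga_index = ruga_index
        self.landmark_index = landmark_index


class ConstantVectorError(RugometryError, ValueError):
    """A descriptor vector has zero variance; Pearson r is undefined."""


class MissingDataError(RugometryError, ValueError):
    """A summary cell has no values."""


class DegenerateTestError(RugometryError, ValueError):
    """A rank test cannot be computed (e.g. every value tied)."""


class GenerationError(RugometryError, ValueError):
    """A synthetic-palate specification yields no valid landmark protocol."""
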