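"""Exception hierarchy for musclemorph."""


class MuscleMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(MuscleMorphError, ValueError):
    """A contour, stack, profile or spec violates a documented invariant."""


class ParseError(MuscleMorphError, ValueError):
    """A file does not conform to the documented schema."""


class DegenerateGeometryError(ValidationError):
    """A polygon has fewer than 3 vertices or (numerically) zero area."""


class InfeasibleSpecError(ValidationError):
    """A synthetic-data specification lies outside the attainable set."""
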