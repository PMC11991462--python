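"""Exception types shared across the package."""


class RadiopeekError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(RadiopeekError):
    """A chemical formula string could not be parsed.

    Carries the character ``position`` of the offending token.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class DomainError(RadiopeekError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class RangeError(RadiopeekError, ValueError):
    """An energy query falls outside the span of a tabulated grid."""


class LookupError_(RadiopeekError, KeyError):
    """A requested element or material is missing from a library."""


class GeometryError(RadiopeekError, ValueError):
    """Simulation geometry is invalid (e.g. overlapping volumes)."""


class ResolutionError(RadiopeekError, ValueError):
    """A grid is too coarse for the requested analysis."""
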