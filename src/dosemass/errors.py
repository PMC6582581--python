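"""Exception hierarchy shared across the package."""


class DosemassError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(DosemassError):
    """Inconsistent or incompatible spatial geometry (spacing, extent, frames)."""


class FormatError(DosemassError):
    """Unsupported or malformed file format."""


class ContourParseError(DosemassError):
    """Structure/contour data violates its preconditions (e.g. <3 points)."""


class RasterizationError(DosemassError):
    """A contour could not be assigned to a grid slice."""


class EmptyStructureError(DosemassError):
    """An operation that needs a non-empty structure received an empty one."""


class DataError(DosemassError):
    """Physically invalid data values (e.g. negative mass density)."""


class ParameterError(DosemassError):
    """Invalid user-supplied parameters."""


class MissingStructureError(DosemassError):
    """A required named structure is absent from a structure set."""

    def __init__(self, names):
        self.names = tuple(names)
        super().__init__(f"missing required structure(s): {', '.join(self.names)}")


class StatisticsError(DosemassError):
    """A statistical operation is undefined for the given input."""
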