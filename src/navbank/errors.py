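"""Exception types shared across the package."""


class NavbankError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(NavbankError, ValueError):
    """A coordinate lies outside the map's dimensions."""


class DuplicateCoordinateError(NavbankError, ValueError):
    """Two objects were placed on the same cell."""


class ValidationError(NavbankError, ValueError):
    """An input violates a structural precondition."""


class UnsupportedPrimitiveError(NavbankError, ValueError):
    """The instruction's action word has no implemented primitive."""


class CoverageError(NavbankError, KeyError):
    """The distance table does not cover a location the planner needs."""


class StateError(NavbankError, RuntimeError):
    """An operation was called before its prerequisite step."""


class SizeError(NavbankError, ValueError):
    """The instance is too large for exact solution."""


class DegenerateSamplesError(NavbankError, ValueError):
    """Both samples have zero variance; the test statistic is undefined."""


class FormatError(NavbankError, ValueError):
    """A file does not parse as the expected format."""
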