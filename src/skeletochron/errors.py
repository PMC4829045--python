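"""Exception hierarchy for the skeletochronology pipeline."""


class SkeletochronError(Exception):
    """Base class for all package errors."""


class DomainError(SkeletochronError, ValueError):
    """A numeric argument is outside the mathematically valid domain."""


class AlignmentError(SkeletochronError, ValueError):
    """Two sequences that must be paired 1:1 have incompatible shapes."""


class StructuralError(SkeletochronError, ValueError):
    """Input structure is malformed (e.g. double-LAG flags not in adjacent pairs)."""


class DegenerateSampleError(SkeletochronError, ValueError):
    """A statistic was requested on a sample with no usable information."""


class EmptyProfileError(SkeletochronError, ValueError):
    """A bone profile with no LAGs was passed where at least one is required."""


class LagResorbedError(SkeletochronError, LookupError):
    """The growth mark matching the target date lies inside the resorption core.

    Callers should fall back to the OTC mark diameter when one is available.
    """


class ParameterError(SkeletochronError, ValueError):
    """A configuration parameter violates its documented constraint."""


class DataAvailabilityError(SkeletochronError, ValueError):
    """A required optional measurement (e.g. OTC mark diameter) is missing."""


class RowError(SkeletochronError, ValueError):
    """A CSV row failed to parse; carries file and line context."""

    def __init__(self, message: str, source: str = "", line: int | None = None):
        loc = f"{source}:{line}: " if line is not None else (f"{source}: " if source else "")
        super().__init__(f"{loc}{message}")
        self.source = source
        self.line = line


class SchemaError(SkeletochronError, ValueError):
    """A CSV file is missing required columns."""
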