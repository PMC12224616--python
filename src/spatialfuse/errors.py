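"""Exception hierarchy for spatialfuse."""


class SpatialFuseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpatialFuseError):
    """Input violates a documented invariant (shapes, IDs, parameter ranges)."""


class FormatError(SpatialFuseError):
    """A file could not be parsed under the declared format."""


class AlignmentError(SpatialFuseError):
    """Spot sets of the provided inputs cannot be reconciled."""


class TrainingError(SpatialFuseError):
    """Optimization produced a non-finite loss or otherwise failed."""
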