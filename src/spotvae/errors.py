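"""Exception types raised across the package."""


class SpotVAEError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpotVAEError):
    """A file did not conform to the expected on-disk format."""


class IncompatibleError(SpotVAEError):
    """Two objects cannot be combined (e.g. disjoint gene spaces)."""


class EstimationError(SpotVAEError):
    """Signature estimation preconditions violated."""


class ShapeError(SpotVAEError):
    """Dimension mismatch between model and data."""


class DomainError(SpotVAEError):
    """A numeric argument is outside its valid domain."""
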