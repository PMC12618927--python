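"""Exception hierarchy used across the codec."""


class WavecalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WavecalError):
    """A parameter value is out of its documented range."""


class DimensionError(WavecalError):
    """An image is too small (or oddly shaped) for the requested operation."""


class StructuralError(WavecalError):
    """Mismatched shapes / inconsistent composite objects."""


class FormatError(WavecalError):
    """A bitstream or payload failed validation (corrupt, truncated,
    wrong magic, checksum mismatch)."""


class NumericalError(WavecalError):
    """Non-finite values appeared where finite ones are required."""


class ZeroVarianceError(WavecalError):
    """A correlation was requested on zero-variance data."""


class UsageError(WavecalError):
    """API misuse: empty inputs, untrained model, mismatched model hash."""
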