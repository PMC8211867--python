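"""Exception types shared across the pipeline."""


class OBCIError(Exception):
    """Base class for all package errors."""


class ConfigError(OBCIError, ValueError):
    """Invalid session or pipeline configuration."""


class InputError(OBCIError, ValueError):
    """Malformed or empty input data."""


class AlignmentError(OBCIError, ValueError):
    """Inputs are not mutually consistent in time."""


class InsufficientDataError(OBCIError, ValueError):
    """Not enough trials / ROIs / frames for the requested analysis."""


class NumericError(OBCIError, ArithmeticError):
    """Numerically invalid intermediate (e.g. non-positive baseline)."""
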