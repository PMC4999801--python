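"""Exception hierarchy for the pipeline.

Every failure mode maps to one of these so the CLI can turn any pipeline
error into a nonzero exit with a readable message.
"""


class Ki67QuantError(Exception):
    """Base class for all package errors."""


class InputError(Ki67QuantError):
    """Unreadable, corrupt or otherwise unusable input file."""


class DimensionError(Ki67QuantError):
    """Image too small for the requested window/filter support."""


class DegenerateInputError(Ki67QuantError):
    """Input with too little variation to support the operation
    (e.g. a uniform image offers fewer than three distinct pixel features)."""


class DomainError(Ki67QuantError):
    """Scalar argument outside its mathematical domain."""


class InsufficientDataError(Ki67QuantError):
    """Not enough non-null observations to aggregate."""


class PlacementError(Ki67QuantError):
    """Synthetic scene could not be packed within the attempt budget."""


class ConfigError(Ki67QuantError):
    """Unknown or invalid configuration key/value."""
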