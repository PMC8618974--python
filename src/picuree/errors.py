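"""Exception hierarchy shared across the pipeline.

CLI exit-code mapping: :class:`ConfigurationError` -> 2,
:class:`DataError` -> 3; everything else is a bug.
"""


class PicureeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PicureeError):
    """Invalid configuration value; names the offending field."""


class DataError(PicureeError):
    """Input data violates a precondition (NaNs, bad shapes, bad values)."""


class DomainError(PicureeError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class AvailabilityError(PicureeError):
    """A reference value is unavailable (e.g. abscissa outside a growth grid)."""
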