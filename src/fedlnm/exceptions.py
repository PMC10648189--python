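"""Exception hierarchy.

Everything user-facing raises a subclass of :class:`FedLNMError` so callers
(and the CLI) can catch one type.
"""


class FedLNMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedLNMError, ValueError):
    """Invalid configuration value (bad proportion, non-positive size, unknown key)."""


class InputError(FedLNMError, ValueError):
    """Malformed runtime input (length mismatch, empty input, wrong shape)."""


class QuotaError(FedLNMError, ValueError):
    """A client partition asked for more records of a class than the cohort holds."""


class SchemaError(FedLNMError, ValueError):
    """A file does not conform to the declared column schema."""


class AggregationError(FedLNMError, ValueError):
    """Parameter collections passed to FedAvg disagree in names or shapes."""
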