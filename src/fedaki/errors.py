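"""Exception types raised across the pipeline."""


class FedakiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedakiError):
    """Invalid generator, experiment or FL configuration."""


class SchemaError(FedakiError):
    """A stay is missing a field a pipeline stage requires."""


class BaselineUnavailableError(FedakiError):
    """No eligible baseline creatinine value exists for a stay."""


class UndefinedMetricError(FedakiError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class ImputationError(FedakiError):
    """A feature was observed nowhere in the imputer's fitting set."""


class RegistryError(FedakiError):
    """Feature registry mismatch or unknown source stream."""


class TrainingError(FedakiError):
    """Model fitting failed on degenerate input."""
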