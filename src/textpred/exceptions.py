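"""Exception hierarchy shared across the package."""


class TextpredError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TextpredError):
    """Invalid generator, task, or experiment configuration."""


class SchemaError(TextpredError):
    """A table does not conform to the expected relational schema."""


class IntegrityError(TextpredError):
    """Persisted artifacts are inconsistent (dimension/metadata mismatch)."""


class FitError(TextpredError):
    """A pipeline or model could not be fitted (e.g. empty corpus)."""


class SplitError(TextpredError):
    """A subject-level split is impossible (e.g. single-person cohort)."""


class TrainingError(TextpredError):
    """Model training is impossible (e.g. single-class labels)."""


class MetricError(TextpredError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""
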