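"""Exception hierarchy shared across the package."""


class VoaError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(VoaError, ValueError):
    """An invalid simulation or configuration parameter."""


class InputError(VoaError, ValueError):
    """A recording, table, or trace that violates an input contract."""


class SchemaError(VoaError, ValueError):
    """A serialized artifact whose structure does not match the expected schema."""


class CohortError(VoaError, ValueError):
    """A cohort that cannot support the requested use (e.g. an empty class)."""


class DegenerateMetricError(VoaError, ValueError):
    """A metric column with zero variance, which cannot be z-scored."""


class TrainingError(VoaError, ValueError):
    """Training data that cannot support classifier fitting."""


class SelectionError(VoaError, ValueError):
    """An invalid metric-selection request (e.g. empty candidate set)."""


class ConfigurationError(VoaError, ValueError):
    """A step plan or run configuration that is internally inconsistent."""


class MetricComputationError(VoaError, RuntimeError):
    """A registered metric function failed on a recording; names the metric."""


class NumericError(VoaError, ValueError):
    """A non-finite value where a finite one is required."""


class NonUniformSamplingWarning(UserWarning):
    """Sampling intervals vary more than the stated tolerance for finite differences."""
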