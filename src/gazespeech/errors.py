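"""Exception types shared across the pipeline."""


class GazespeechError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazespeechError):
    """Invalid configuration, malformed AoI definitions, missing files."""


class UnsupportedTaskError(GazespeechError):
    """Requested an operation for a task that does not support it."""


class CohortCompositionError(GazespeechError):
    """Cohort lacks the class structure an operation requires."""


class StratificationError(GazespeechError):
    """A cross-validation fold cannot satisfy the stratification contract."""


class ContractViolationError(GazespeechError):
    """An internal pipeline contract was violated (e.g. cross-algorithm fusion)."""
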