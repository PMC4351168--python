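"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ConfigurationError -> 2, ValidationError -> 3.
"""


class ChipConcordError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ChipConcordError):
    """Bad invocation: missing files, unmapped mandatory columns, invalid options."""

    exit_code = 2


class ValidationError(ChipConcordError):
    """Inconsistent data: conflicting coordinates, duplicate probes, missing claims."""

    exit_code = 3


class BuildMismatchError(ValidationError):
    """Query and index carry different genome-build tags; no silent liftover."""


class UndefinedStatisticError(ValidationError):
    """A statistic was requested on an input where its denominator vanishes."""


class InconsistencyError(ValidationError):
    """Printed marginals admit no integer 2x2 split (reconstruction failed)."""
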