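"""Exception hierarchy for summary-statistics validation and pipeline errors."""


class SummaryDataError(ValueError):
    """Base class for invalid summary-statistics input."""


class SchemaError(SummaryDataError):
    """File header or column set does not match the expected dialect."""


class ValidationError(SummaryDataError):
    """A parsed record violates a field invariant (names the record and field)."""


class ConfigurationError(ValueError):
    """Simulation or analysis configuration is internally inconsistent."""


class MonomorphicSnpError(ValueError):
    """A genotype vector is constant and cannot be tested for association."""


class EmptyResultError(RuntimeError):
    """A pipeline stage left zero records; carries the stage name."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no records survived pipeline stage '{stage}'")
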