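"""Exception hierarchy for herdtools."""


class HerdToolsError(Exception):
    """Base class for all herdtools errors."""


class IngestError(HerdToolsError):
    """Raised for unreadable or malformed input files."""


class SchemaError(HerdToolsError):
    """Raised when a table does not match the expected column roster."""

    def __init__(self, message, missing=(), unknown=()):
        super().__init__(message)
        self.missing = list(missing)
        self.unknown = list(unknown)


class ConfigError(HerdToolsError):
    """Raised for invalid configuration (bad rules, infeasible probabilities)."""


class AnalysisError(HerdToolsError):
    """Raised when an analysis cannot be run on the given variables."""
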