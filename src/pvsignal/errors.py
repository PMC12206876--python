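"""Exception hierarchy. CLI exit codes map onto these classes."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class ConfigError(PvSignalError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class FormatError(PvSignalError):
    """Malformed input data file (CLI exit code 3)."""


class EmptyCohortError(PvSignalError):
    """No reports satisfy the index-cohort definition; statistics undefined."""


class DegenerateSampleError(PvSignalError):
    """A sample too small or too degenerate for the requested fit (CLI exit code 4)."""
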