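"""Exception hierarchy shared across the package."""


class OsaDetectError(Exception):
    """Base class for all package errors."""


class ValidationError(OsaDetectError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(OsaDetectError, ValueError):
    """A file is syntactically readable but violates the expected format."""


class TrainingError(OsaDetectError, RuntimeError):
    """Optimization failed (e.g. a non-finite loss)."""
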