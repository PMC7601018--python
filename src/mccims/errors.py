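"""Exception hierarchy for the pipeline."""


class MccImsError(Exception):
    """Base class for all package errors."""


class FormatError(MccImsError):
    """An on-disk artifact does not conform to its dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(MccImsError):
    """An in-memory object violates a domain invariant."""


class PeaxUnavailableError(MccImsError):
    """The optional external PEAX binary could not be run.

    PEAX is an external, academic-use-only tool; the pipeline continues
    with the built-in detection methods when it is absent.
    """
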