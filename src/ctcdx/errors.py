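"""Exception hierarchy shared across the package.

The CLI maps :class:`InputValidationError` to exit code 2 and
:class:`DataFormatError` to exit code 3; library code raises these directly.
"""


class CtcdxError(Exception):
    """Base class for all package-specific errors."""


class InputValidationError(CtcdxError):
    """A parameter, record or configuration value violates its contract."""


class DataFormatError(CtcdxError):
    """An input file is malformed; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
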