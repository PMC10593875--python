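"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/configuration problems -> 2,
I/O and parse problems -> 3.
"""


class PedcosegError(Exception):
    """Base class for all package errors."""


class ParseError(PedcosegError):
    """A malformed input file; carries the offending path/line where known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(PedcosegError):
    """Input parsed but violates a structural invariant."""


class ConfigurationError(PedcosegError):
    """Inconsistent or unusable configuration / parameterization."""
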