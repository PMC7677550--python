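"""Exception hierarchy shared across the package."""


class VRStressError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VRStressError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(VRStressError, ValueError):
    """Not enough samples/intervals/beats to compute the quantity."""


class SchemaError(VRStressError, ValueError):
    """Tabular input does not match the expected columns/ids."""


class SelectionFailureError(VRStressError, RuntimeError):
    """No principal component satisfies the loading constraints."""


class ConfigurationError(VRStressError, ValueError):
    """A run configuration is internally inconsistent or incomplete."""


class ParseError(VRStressError, ValueError):
    """A file could not be parsed; carries the offending location."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
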