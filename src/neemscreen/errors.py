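"""Exception hierarchy shared by every pipeline stage."""


class NeemscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeemscreenError):
    """A parameter or combination of parameters is invalid."""


class SizingError(ConfigurationError):
    """A requested synthetic design cannot be constructed (e.g. barcode space too small)."""


class ConsistencyError(NeemscreenError):
    """Inputs that must agree with each other do not (e.g. planted IDs missing from a library)."""


class DesignError(NeemscreenError):
    """An experimental design requirement is violated (e.g. too few time points, missing control)."""


class ParseError(NeemscreenError):
    """A file could not be parsed; carries location information where available."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ReconciliationError(NeemscreenError):
    """Two inputs that must describe the same samples/genes disagree; lists offenders."""


class DataError(NeemscreenError):
    """Numeric data violates a precondition (non-positive intensity, missing value, ...)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested operation."""


class ValidationError(NeemscreenError):
    """A computed or supplied value is outside its legal range."""
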