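"""Exception hierarchy shared across the pipeline stages."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class ConfigError(HerbnetError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(HerbnetError):
    """An invalid data record (missing/non-numeric field, malformed line...)."""


class ParseError(HerbnetError):
    """A malformed input file; carries the 1-based line number where known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ConvergenceError(HerbnetError):
    """An iterative solver failed to converge; carries the iteration count."""

    def __init__(self, message: str, iterations: int):
        self.iterations = iterations
        super().__init__(f"{message} (after {iterations} iterations)")
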