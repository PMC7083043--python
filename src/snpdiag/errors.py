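"""Exception hierarchy for the workbench.

All package errors derive from :class:`SnpdiagError` so callers can catch
one base class; subclasses mirror the failure modes of the pipeline stages
(configuration, malformed data, file parsing, tree rooting, usage).
"""


class SnpdiagError(Exception):
    """Base class for all errors raised by snpdiag."""


class ConfigurationError(SnpdiagError):
    """Invalid simulation or pipeline configuration."""


class DataError(SnpdiagError):
    """Malformed in-memory data (negative counts, NaN distances, ...)."""


class FormatError(SnpdiagError):
    """Positioned parse error in an input file."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class OrderingError(SnpdiagError):
    """Input records not sorted by (replicon, position)."""


class MissingInputError(SnpdiagError):
    """A panel accession has no corresponding evidence table."""


class RootingError(SnpdiagError):
    """Outgroup is not monophyletic on the unrooted tree."""


class UsageError(SnpdiagError):
    """Operation invoked with arguments that make it undefined."""


class StageError(SnpdiagError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
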