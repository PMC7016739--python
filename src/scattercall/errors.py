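"""Exception hierarchy shared across the toolkit."""


class ScatterCallError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ScatterCallError):
    """A file did not conform to its expected format.

    Carries the offending line number where known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ScatterCallError):
    """An input violated a documented precondition or invariant."""


class RoutingError(ScatterCallError):
    """A record could not be assigned to any genomic region."""


class UndefinedMetricError(ScatterCallError):
    """A concordance metric's denominator is zero."""


class PipelineError(ScatterCallError):
    """A pipeline stage failed; the run aborted at the current barrier."""
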