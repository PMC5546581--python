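"""Exception hierarchy for walkscreen.

All errors raised by the package derive from :class:`WalkscreenError` so
callers can catch one base class at the pipeline boundary.
"""


class WalkscreenError(Exception):
    """Base class for all walkscreen errors."""


class ParseError(WalkscreenError, ValueError):
    """A malformed input line (wrong field count, non-numeric score, ...).

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DataIntegrityError(WalkscreenError, ValueError):
    """Input is syntactically valid but internally inconsistent.

    Example: the same unordered protein pair listed twice with two
    different interaction scores.
    """


class ConfigurationError(WalkscreenError, ValueError):
    """An invalid run configuration (empty seed set, zero permutations, ...)."""


class ConvergenceError(WalkscreenError, RuntimeError):
    """The propagation iteration hit ``max_iter`` before the update norm
    dropped below tolerance.  ``final_delta`` holds the last change."""

    def __init__(self, message: str, final_delta: float, iterations: int):
        super().__init__(message)
        self.final_delta = final_delta
        self.iterations = iterations


class OntologyError(WalkscreenError, ValueError):
    """The term ontology violates its contract (e.g. a cycle in is_a)."""


class ConsistencyError(WalkscreenError, ValueError):
    """Score maps handed to the screening stage do not cover every gene."""


class LookupError_(WalkscreenError, KeyError):
    """A node identifier is not present in the network."""


class GenerationError(WalkscreenError, RuntimeError):
    """The synthetic generator could not satisfy its spec after retries."""


class PipelineStageError(WalkscreenError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
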