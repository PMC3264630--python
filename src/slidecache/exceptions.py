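"""Exception types shared across the package."""


class SlideCacheError(Exception):
    """Base class for all slidecache errors."""


class LevelNotFoundError(SlideCacheError, LookupError):
    """A magnification was requested that is not stored in the pyramid."""


class AnnotationStateError(SlideCacheError, RuntimeError):
    """An annotation operation was issued in the wrong session mode."""


class AnnotationFileError(SlideCacheError, ValueError):
    """An annotation file could not be parsed.

    Carries the offending record index (0-based) in ``record`` when known.
    """

    def __init__(self, message: str, record: int | None = None):
        super().__init__(message)
        self.record = record


class TraceError(SlideCacheError, ValueError):
    """A manipulation/annotation trace is malformed or violates the
    annotation state machine.  ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
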