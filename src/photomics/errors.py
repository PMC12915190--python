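"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ParameterError` and :class:`DataError`
(including subclasses) exit with code 1 (validation failure); any other
exception exits with code 2 (runtime failure).
"""


class PhotomicsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhotomicsError, ValueError):
    """A user-supplied parameter violates its documented invariant."""


class DataError(PhotomicsError, ValueError):
    """Input data violates a documented contract (NaNs, bad schema, ...)."""


class FormatError(DataError):
    """A file could not be parsed under the documented dialect."""


class DegenerateFitError(DataError):
    """A fit or baseline estimate is degenerate (e.g. zero variance)."""


class EmptyResultError(PhotomicsError):
    """An operation produced no usable rows; carries diagnostic counts."""

    def __init__(self, message: str, n_candidates: int = 0, n_dropped: int = 0):
        super().__init__(message)
        self.n_candidates = n_candidates
        self.n_dropped = n_dropped
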