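"""Exception hierarchy for dmreg.

All library errors derive from :class:`DmregError` so callers (and the CLI)
can catch one base class.
"""


class DmregError(Exception):
    """Base class for all dmreg errors."""


class InvalidInputError(DmregError, ValueError):
    """Raised when data passed to an operation is malformed (non-finite,
    empty, wrong shape, out of range)."""


class InvalidParameterError(DmregError, ValueError):
    """Raised when a model or procedure parameter is outside its domain."""


class SampleTooSmallError(DmregError, ValueError):
    """Raised when the sample is too small for the requested fit."""


class FitFailedError(DmregError, RuntimeError):
    """Raised when maximum-likelihood fitting cannot produce a usable model
    (e.g. the mean residual cosine is non-positive at the optimum)."""


class LeaveOneOutFitError(FitFailedError):
    """Raised when a leave-one-out refit fails; records which observation
    was deleted (1-based)."""

    def __init__(self, deleted: int, cause: Exception):
        self.deleted = deleted
        super().__init__(
            f"leave-one-out refit failed after deleting observation {deleted}: {cause}"
        )
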