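"""Exception taxonomy shared across the package.

Every anticipated failure mode raises a subclass of :class:`PetsurvError`
so callers can distinguish analysis degeneracies (no events, empty strata,
inadmissible cutoffs) from genuine bugs.
"""


class PetsurvError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PetsurvError):
    """A configuration object violates its invariants."""


class CohortValidationError(PetsurvError):
    """A cohort table failed validation; carries the offending row (0-based

    data row, excluding header) when applicable."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class NoEventsError(PetsurvError):
    """A survival fit was requested on data without any observed events."""


class DegenerateCovariateError(PetsurvError):
    """A covariate is constant across all patients in the fit."""


class CollinearDesignError(PetsurvError):
    """The design matrix is (numerically) rank deficient."""


class MonotoneLikelihoodError(PetsurvError):
    """The Cox partial likelihood is monotone: the MLE is infinite.

    Typical cause: all events fall in one binarized group.  ``direction``
    is +1 if the coefficient diverges to +inf, -1 for -inf.
    """

    def __init__(self, covariate: str, direction: int):
        self.covariate = covariate
        self.direction = direction
        arrow = "+inf" if direction > 0 else "-inf"
        super().__init__(
            f"monotone partial likelihood: coefficient of {covariate!r} "
            f"diverges to {arrow} (infinite hazard ratio)"
        )


class ConvergenceError(PetsurvError):
    """An iterative procedure failed to converge.

    For the delineator, ``history`` carries the last two region volumes (ml)."""

    def __init__(self, message: str, history: tuple | None = None):
        self.history = history
        super().__init__(message)


class NoLesionAtSeedError(PetsurvError):
    """A delineation seed lies below the adaptive threshold at the first

    iteration (pure background)."""


class NoAdmissibleCutoffError(PetsurvError):
    """No candidate cutoff satisfies the admissibility rule."""


class DegenerateResamplesError(PetsurvError):
    """Too many bootstrap resamples were degenerate to trust the p-value."""
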