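"""Exception hierarchy for vulnmeta.

All package-specific errors derive from :class:`VulnmetaError` so callers can
catch everything the library raises with a single except clause.
"""


class VulnmetaError(Exception):
    """Base class for all vulnmeta errors."""


class InvalidTableError(VulnmetaError):
    """A 2x2 table cannot support the requested estimate (e.g. empty row)."""


class DegenerateEstimateError(VulnmetaError):
    """A zero cell makes the estimate infinite and correction is disabled."""


class UndefinedTestError(VulnmetaError):
    """The requested test is undefined for the input (e.g. monomorphic HWE)."""


class NoDataError(VulnmetaError):
    """An operation received an empty collection of estimates."""


class InsufficientStudiesError(VulnmetaError):
    """Too few studies for the requested model (meta-regression needs k >= 3)."""


class RankDeficientError(VulnmetaError):
    """The moderator is constant, so the regression design matrix is singular."""


class ConvergenceError(VulnmetaError):
    """Iterative variance estimation failed to converge.

    Carries the last iterate so callers can inspect how far the fit got.
    """

    def __init__(self, message: str, tau2_last: float):
        super().__init__(message)
        self.tau2_last = tau2_last


class ParameterizationError(VulnmetaError):
    """A risk-model parameterization produces probabilities outside (0, 1)."""


class SchemaError(VulnmetaError):
    """An input file violates the study-level CSV schema.

    ``problems`` is a list of human-readable messages with 1-based line numbers.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid study CSV:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
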