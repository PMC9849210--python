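"""Exception hierarchy.

All package errors derive from :class:`AssrConnError` so callers can catch
one base class; subclasses distinguish configuration problems from data
pathologies that arise at run time.
"""


class AssrConnError(Exception):
    """Base class for all assrconn errors."""


class ConfigurationError(AssrConnError, ValueError):
    """Invalid parameter or configuration value."""


class DegenerateDataError(AssrConnError):
    """Input data are degenerate for the requested operation.

    Examples: rank-deficient covariance below the minimum retained rank,
    a constant map passed to the smoothness estimator, zero background
    power in the normalization ratio.
    """


class InsufficientDataError(AssrConnError):
    """Too few frames/trials/subjects remain to proceed."""


class DesignError(AssrConnError):
    """A regression design matrix is rank deficient or ill conditioned."""


class ResolutionError(AssrConnError):
    """Spectral resolution cannot express the requested band arithmetic."""
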