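"""Exception types shared across the package."""


class SCCSPError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SCCSPError, ValueError):
    """A configuration value violates its documented constraints."""


class ValidationError(SCCSPError, ValueError):
    """An input array or container fails a shape/finiteness/label check."""


class FormatError(SCCSPError, ValueError):
    """A file parsed, but required fields (events, sidecar keys) are missing."""


class RankDeficiencyError(SCCSPError, ValueError):
    """A covariance or spectral matrix is numerically rank deficient.

    Raised instead of silently regularizing; callers may add a ridge
    ``eps * I`` to the offending matrix if that is acceptable for their data.
    """


class DegenerateDataError(SCCSPError, ValueError):
    """Data are degenerate for the requested statistic (zero power, D = 0, pe = 1)."""
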