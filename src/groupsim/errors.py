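"""Exception hierarchy shared across the package."""


class GroupsimError(Exception):
    """Base class for all package-specific errors."""


class DegenerateVarianceError(GroupsimError):
    """Raised when a standardized statistic is undefined because the
    variance denominator is zero (both groups constant)."""


class ConfigError(GroupsimError):
    """Raised on invalid survey configuration or generator settings."""
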