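"""Exception hierarchy for marsalt.

All errors derive from :class:`MarsaltError` so callers can catch the
package's failures with a single except clause; parameter-validation
errors additionally derive from :class:`ValueError` so that generic
validation code keeps working.
"""


class MarsaltError(Exception):
    """Base class for all marsalt errors."""


class InvalidParameterError(MarsaltError, ValueError):
    """A physical or protocol parameter violates its domain invariant."""


class BelowThresholdError(MarsaltError, ValueError):
    """Shear velocity below the impact threshold: no sustained saltation."""


class OutOfRangeError(MarsaltError, ValueError):
    """Survival-curve evaluation outside the anchor range with
    extrapolation disabled."""


class FitError(MarsaltError, ValueError):
    """Survival-model fit is degenerate (too few or invalid points)."""


class ConfigurationError(MarsaltError, ValueError):
    """Pipeline configuration is missing keys or holds invalid values."""
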