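"""Exception hierarchy.

Validation errors signal malformed data or broken invariants; configuration
errors signal unusable settings. Both derive from ValueError so callers who
do not care about the distinction can catch the builtin.
"""


class CystfuseError(Exception):
    """Base class for all package errors."""


class ValidationError(CystfuseError, ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(CystfuseError, ValueError):
    """A configuration object is internally inconsistent or unusable."""
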