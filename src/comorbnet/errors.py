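"""Exception hierarchy for comorbnet.

All errors raised by the package derive from :class:`ComorbnetError` so a
caller can catch pipeline failures with one handler while format, row and
configuration problems stay distinguishable.
"""


class ComorbnetError(Exception):
    """Base class for all comorbnet errors."""


class FormatError(ComorbnetError):
    """A table violates its declared schema (missing column, bad vocabulary)."""


class RowError(ComorbnetError):
    """A single row of an input table could not be parsed or validated."""


class ConfigError(ComorbnetError):
    """A run configuration is invalid (unknown key, missing path, bad value)."""


class InfeasibleSpecError(ComorbnetError):
    """A synthetic-fixture specification is internally inconsistent."""
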