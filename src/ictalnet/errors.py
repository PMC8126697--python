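"""Exception hierarchy shared across the package."""


class IctalnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IctalnetError, ValueError):
    """An object or argument violates a documented invariant."""


class FormatError(IctalnetError, ValueError):
    """A file on disk does not conform to the expected layout."""


class SchemaError(IctalnetError, ValueError):
    """A tabular input is missing required columns or rows."""


class InfeasibleError(IctalnetError, ValueError):
    """A requested selection cannot be satisfied by the available data."""
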