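"""Exception types shared across the package."""


class PlastisinkError(Exception):
    """Base class for package errors."""


class DomainError(PlastisinkError, ValueError):
    """An input lies outside the physical domain an operation is valid for.

    The message always names the offending field.
    """


class ConfigError(PlastisinkError, ValueError):
    """A configuration object is inconsistent or incomplete."""
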