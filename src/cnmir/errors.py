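"""Exception hierarchy shared across the package."""


class CnmirError(Exception):
    """Base class for all package errors."""


class ParseError(CnmirError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CnmirError, ValueError):
    """Parsed content violates a documented invariant."""


class ConfigError(CnmirError, ValueError):
    """A configuration object or file is invalid."""
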