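"""Exception hierarchy shared across stemhet modules."""


class StemhetError(Exception):
    """Base class for all stemhet errors."""


class ConfigError(StemhetError):
    """A configuration object or file is invalid or self-inconsistent."""


class InputError(StemhetError):
    """A data table or argument violates a precondition."""


class ParseError(InputError):
    """A file could not be parsed; message names the offending line."""
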