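class ChialoopError(Exception):
    """Base class for all errors raised by chialoop."""


class ParseError(ChialoopError):
    """Malformed input file."""
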