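"""Exception hierarchy shared across the package."""


class MycopanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MycopanError, ValueError):
    """Input violates a structural invariant (duplicates, unknown ids, vocabulary)."""


class ParseError(MycopanError, ValueError):
    """A file could not be parsed; message carries row/column coordinates."""
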