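"""Exception hierarchy shared across the package."""


class CrosspeakError(Exception):
    """Base class for all package errors."""


class FormatError(CrosspeakError, ValueError):
    """A file could not be parsed into the expected record structure."""


class ValidationError(CrosspeakError, ValueError):
    """Parsed data violated a domain invariant (coordinates, vocabulary, ids)."""
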