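"""Exception hierarchy."""


class DomevolError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DomevolError):
    """Input is well-formed but violates a semantic precondition."""


class FormatError(DomevolError):
    """Input text could not be parsed."""


class InvalidArrangementError(ValidationError):
    """A domain identifier or arrangement violates its invariants."""
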