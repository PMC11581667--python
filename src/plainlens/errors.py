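"""Exception hierarchy shared across the package."""


class PlainLensError(Exception):
    """Base class for all package errors."""


class EmptyDocumentError(PlainLensError):
    """Raised when a text to be scored is empty or whitespace-only."""


class DomainError(PlainLensError):
    """Raised when an operation receives input outside its domain
    (e.g. a non-alphabetic token passed to the syllable counter)."""


class LexiconError(PlainLensError):
    """Raised when a lexicon resource file is malformed."""


class ValidationError(PlainLensError):
    """Raised when trial records or generator specs violate their schema."""
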