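"""Exception hierarchy shared across the package."""


class EmbedsepError(Exception):
    """Base class for all package errors."""


class ValidationError(EmbedsepError, ValueError):
    """An input object violates its invariants or a precondition."""


class ParseError(EmbedsepError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConsistencyError(ValidationError):
    """Cross-file or cross-table identifiers disagree."""


class GeneLookupError(EmbedsepError, KeyError):
    """An unknown gene was requested; the message lists near-matches."""
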