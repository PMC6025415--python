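"""Exception hierarchy shared across the pipeline stages."""


class CdomPaeError(Exception):
    """Base class for all package errors."""


class ValidationError(CdomPaeError, ValueError):
    """Input violates a documented invariant (axes, ranges, units, labels)."""


class ParseError(CdomPaeError, ValueError):
    """A file does not follow the documented dialect."""


class MissingInputError(CdomPaeError, FileNotFoundError):
    """A required input file or column is absent."""


class UncorrectedEEMError(ValidationError):
    """An EEM reached integration without the required corrections."""
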