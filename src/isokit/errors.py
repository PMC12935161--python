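"""Exception hierarchy shared across the toolkit."""


class IsokitError(Exception):
    """Base class for all toolkit errors."""


class GtfParseError(IsokitError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(IsokitError):
    """A domain object violates one of its structural invariants."""


class CoordinateError(IsokitError):
    """A coordinate lies outside the domain of the requested transform."""


class SchemaError(IsokitError):
    """A tabular input is missing required columns or has ill-typed values."""
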