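"""Exception hierarchy shared by all pipeline stages."""


class CernaPipeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CernaPipeError, ValueError):
    """Inputs violate a precondition (inconsistent counts, bad range, ...)."""


class InsufficientDataError(CernaPipeError, ValueError):
    """Too few observations / groups / events to run the requested test."""


class DegenerateDataError(CernaPipeError, ValueError):
    """Inputs are formally valid but carry no usable variation."""


class DegenerateSplitError(DegenerateDataError):
    """A high/low split cannot be formed (e.g. constant expression)."""


class NoCutpointError(CernaPipeError, ValueError):
    """No admissible candidate threshold exists for the cutpoint scan."""


class UndefinedSetError(CernaPipeError, ValueError):
    """A gene set is empty or degenerate after intersection with the universe."""


class FormatError(InvalidInputError):
    """A file does not conform to its declared tabular format."""
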