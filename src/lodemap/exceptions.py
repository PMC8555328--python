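"""Exception hierarchy for lodemap.

All package errors derive from :class:`LodemapError` so callers (and the
CLI) can catch them uniformly; parse and validation failures carry a
human-readable location where one exists.
"""


class LodemapError(Exception):
    """Base class for all lodemap errors."""


class ParseError(LodemapError):
    """A file could not be parsed; the message names the offending row/column."""


class ValidationError(LodemapError):
    """Input data violates a structural invariant (duplicates, overlaps, ...)."""


class ParameterError(LodemapError):
    """An argument is outside its documented domain."""


class AnalysisError(LodemapError):
    """An analysis cannot run on the given data (e.g. too few LD pairs)."""


class ContractError(LodemapError):
    """An internal precondition was violated by the caller."""
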