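"""Exception hierarchy for gramprod.

All errors raised by the library derive from :class:`GramprodError` so CLI
wrappers can catch one type and print a one-line diagnosis.
"""


class GramprodError(Exception):
    """Base class for all gramprod errors."""


class UnknownParadigmError(GramprodError):
    """Requested paradigm name is not registered and is not a readable file."""


class ParadigmConfigError(GramprodError):
    """A paradigm definition violates its invariants (duplicate slots,
    dangling allomorphs, empty inventory)."""


class UnknownMarkerError(GramprodError):
    """A surface marker could not be mapped to a paradigm slot in strict mode."""


class TokenFormatError(GramprodError):
    """A token-list record is malformed; carries the line number and text."""

    def __init__(self, message: str, line_no: int | None = None, text: str | None = None):
        self.line_no = line_no
        self.text = text
        super().__init__(message)


class EmptySampleError(GramprodError):
    """A token sample contains no tokens where at least one is required."""


class NoSharedLexemesError(GramprodError):
    """The two samples have no lemma in common; the lexical control removes
    everything and no comparison is possible."""


class MatchSizeError(GramprodError):
    """The resolved subsample size cannot be drawn from the available tokens."""


class LemmaMismatchError(GramprodError):
    """Two per-lemma profiles are defined on different lemma sets."""
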