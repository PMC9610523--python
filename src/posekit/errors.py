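"""Exception hierarchy."""


class PosekitError(Exception):
    """Base class for all package errors."""


class UnsupportedFormatError(PosekitError):
    """Filename extension or dialect not supported."""


class ParseError(PosekitError):
    """A structure record could not be parsed."""

    def __init__(self, message: str, record_index: int | None = None):
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)
        self.record_index = record_index


class CapacityError(PosekitError):
    """Output format cannot hold the molecule (e.g. V2000 atom cap)."""


class IncompatibleMoleculesError(PosekitError):
    """Reference and probe cannot correspond (element multiset mismatch)."""


class MatchingFailureError(PosekitError):
    """No complete atom mapping found within the backtrack budget."""


class NotAPeptideError(PosekitError):
    """Backbone mode requested for a molecule without a peptide motif."""


class InputSizeError(PosekitError):
    """Input file exceeds the size cap."""
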