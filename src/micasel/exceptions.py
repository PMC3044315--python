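"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`MicaselError`
so callers (and the CLI) can map error classes to exit codes.
"""


class MicaselError(Exception):
    """Base class for all micasel errors."""


class FormatError(MicaselError):
    """Structurally malformed input file (ragged rows, missing header)."""


class ParseError(MicaselError):
    """A cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row: str | int | None = None,
                 column: str | int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class LabelError(MicaselError):
    """Label file inconsistent with the expression matrix."""


class DomainError(MicaselError):
    """Value outside the mathematical domain of an operation."""


class AlignmentError(MicaselError):
    """Gene or sample identifiers do not line up between two objects."""


class ConsistencyError(MicaselError):
    """An object's internal bookkeeping was tampered with or corrupted."""


class ConvergenceError(MicaselError):
    """Iterative fit failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class DegenerateVarianceError(MicaselError):
    """A variance needed as a denominator is exactly zero."""


class RankError(MicaselError):
    """A matrix required to be full rank is singular."""


class ProtocolError(MicaselError):
    """A cross-validation protocol cannot be carried out on the given data."""
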