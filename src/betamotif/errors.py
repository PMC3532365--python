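"""Exception hierarchy for betamotif."""


class BetaMotifError(Exception):
    """Base class for all betamotif errors."""


class FormatError(BetaMotifError):
    """Malformed β-matrix record text (ragged rows, missing header, ...)."""


class AlphabetError(FormatError):
    """A cell character outside the residue alphabet, gap, or wildcard."""


class ValidationError(BetaMotifError):
    """A structurally invalid β-matrix (all-gap line, split strand, ...)."""


class UnprojectableError(BetaMotifError):
    """A β-graph that cannot be flattened onto a 2D grid.

    Raised for bifurcated sheets (a strand bridging more than two partner
    strands), barrels (cyclic strand adjacency), and register conflicts where
    two bridges force one residue into two different columns.
    """


class MalformedQueryError(ValidationError):
    """A query whose trimers do not form a single connected overlap graph."""


class DuplicateSheetIdError(BetaMotifError):
    """Two matrices with the same sheet id submitted for indexing."""


class IndexIOError(BetaMotifError):
    """Unreadable, corrupt, or version-incompatible index file."""


class DsspFormatError(FormatError):
    """Unparseable DSSP file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number
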