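"""Exception hierarchy shared across the package."""


class NJMergeError(Exception):
    """Base class for all package errors."""


class NewickParseError(NJMergeError):
    """Malformed Newick input."""


class TreeError(NJMergeError):
    """Invariant violation on a tree (duplicate labels, unknown leaf, ...)."""


class DegenerateInputError(NJMergeError):
    """Input too small for the requested operation."""


class MatrixError(NJMergeError):
    """Malformed or inconsistent distance matrix."""


class SaturationError(MatrixError):
    """A pairwise divergence matrix is too saturated for a finite log-det
    distance (non-positive determinant or a zero base-frequency marginal)."""


class AlignmentError(NJMergeError):
    """Malformed alignment (ragged rows, duplicate labels, ...)."""


class NJMergeFailure(NJMergeError):
    """Raised when no remaining siblinghood proposal can be accepted without
    violating pairwise compatibility of the constraint trees.

    Carries the join log accumulated up to the failure point.
    """

    def __init__(self, message, join_log=None):
        super().__init__(message)
        self.join_log = list(join_log or [])


class ExternalMethodError(NJMergeError):
    """An external subset-tree command failed or produced unusable output."""
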