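"""Exception hierarchy for polxscan."""


class PolxScanError(Exception):
    """Base class for all polxscan errors."""


class AlignmentShapeError(PolxScanError):
    """Rows of an alignment do not all have the same length."""


class AlphabetError(PolxScanError):
    """A sequence contains a character outside the allowed alphabet."""


class AnchorRangeError(PolxScanError, KeyError):
    """A reference residue number falls outside the mapped span."""


class TableValidationError(PolxScanError, ValueError):
    """A gene-table row failed validation."""


class DegenerateTableError(PolxScanError, ValueError):
    """A contingency table is unsuitable for an independence test."""


class ContractError(PolxScanError, ValueError):
    """A precondition of an operation was violated by the caller."""
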