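"""Exception hierarchy.

``PlastBarcodeError`` covers everything raised deliberately by this package;
``FormatError`` marks malformed input files, ``DataError`` marks inputs that
parse but violate a contract (ragged alignments, duplicate ids, impossible
parameter combinations).  The CLI maps these to exit code 1, reserving 2 for
usage errors.
"""


class PlastBarcodeError(Exception):
    """Base class for all errors raised by plastbarcode."""


class FormatError(PlastBarcodeError):
    """A file could not be parsed (bad FASTA/TSV/Newick syntax)."""


class DataError(PlastBarcodeError):
    """Input parsed but violates an invariant or precondition."""
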