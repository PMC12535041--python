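"""Exception types raised across the package."""


class SparseSAError(Exception):
    """Base class for all sparsesa errors."""


class AlphabetError(SparseSAError):
    """Invalid alphabet construction or encoding input."""


class PackingError(SparseSAError):
    """k-mer packing cannot be represented in a machine word."""


class SortingError(SparseSAError):
    """Suffix-sorting precondition violated."""


class SearchError(SparseSAError):
    """Pattern-search precondition violated."""


class FastaError(SparseSAError):
    """Malformed FASTA input or separator collision."""


class IndexFormatError(SparseSAError):
    """Corrupt, truncated or foreign index stream."""
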