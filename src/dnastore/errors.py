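"""Exception hierarchy for the DNA storage toolkit.

Every error raised by this package derives from :class:`DNAStoreError`, so
callers can catch one base class at pipeline boundaries (CLI, end-to-end
runner) while tests assert on the specific subclass.
"""


class DNAStoreError(Exception):
    """Base class for all errors raised by dnastore."""


class AlphabetError(DNAStoreError):
    """A sequence contains characters outside {A, C, G, T}."""


class PrimerDesignError(DNAStoreError):
    """Rejection sampling exhausted its attempt budget; the requested
    library size is infeasible under the given constraints."""


class FormatError(DNAStoreError):
    """A byte record or fragment does not follow the declared layout."""


class TruncatedRecordError(FormatError):
    """A byte record is shorter than its fixed header."""


class FieldRangeError(FormatError):
    """An integer field exceeds its fixed-width range."""


class MissingFileError(DNAStoreError):
    """The requested file identifier is not present in the container set
    or the pool manifest."""


class DanglingToolError(DNAStoreError):
    """A separately-stored record references a tool FID that does not
    resolve to any tool record."""


class UnknownToolError(DNAStoreError):
    """No decompressor is registered for a tool (by FID or by blob)."""


class CapacityError(DNAStoreError):
    """Fragment payload capacity is non-positive; the fragment layout
    cannot exist at these lengths."""


class AddressOverflowError(DNAStoreError):
    """A stream needs more fragments than the address field can index."""


class AssemblyGapError(DNAStoreError):
    """Fragment addresses do not form a complete 0..k range."""

    def __init__(self, missing, c_flag=None):
        self.missing = sorted(missing)
        self.c_flag = c_flag
        super().__init__(f"missing fragment addresses: {self.missing}")


class AssemblyConflictError(DNAStoreError):
    """Two fragments claim the same address with different payloads, or a
    fragment address lies beyond the expected stream extent."""


class SharingLimitError(DNAStoreError):
    """The number of data files sharing one tool violates
    0 < n < floor(L_s / L_p)."""


class DecodeError(DNAStoreError):
    """A nucleotide stream cannot be decoded back to bytes."""

    def __init__(self, message, position=None):
        self.position = position
        super().__init__(message if position is None
                         else f"{message} (position {position})")
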