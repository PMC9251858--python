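"""Exception types shared across the package."""


class BtukitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BtukitError):
    """Cross-referenced input artifacts are inconsistent (ID mismatches, etc.)."""


class ParseError(BtukitError):
    """An input file could not be parsed."""


class EmptyDatasetError(BtukitError):
    """A filtering step removed every sample (or every ASV)."""


class UntestableError(BtukitError):
    """A unit does not meet the minimal sample/species requirements for a test."""


class UndefinedDistanceError(BtukitError):
    """A pairwise distance is undefined (e.g. zero comparable alignment sites)."""
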