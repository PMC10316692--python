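"""Exception hierarchy for squigmap.

Every error raised on a user-facing code path derives from
:class:`SquigmapError`, so callers can catch one type at pipeline
boundaries (e.g. per-read in a batch) without masking programming errors.
"""


class SquigmapError(Exception):
    """Base class for all squigmap errors."""


class FormatError(SquigmapError):
    """A file does not conform to its declared format."""


class AlphabetError(SquigmapError):
    """A sequence contains characters outside the accepted alphabet."""


class KmerLookupError(SquigmapError):
    """A k-mer required for signal synthesis is missing from the pore model."""

    def __init__(self, kmer: str, position: int):
        self.kmer = kmer
        self.position = position
        super().__init__(
            f"k-mer {kmer!r} at sequence position {position} is not in the pore model"
        )


class DegenerateSignalError(SquigmapError):
    """A signal has zero variance and cannot be z-normalized."""


class SizeError(SquigmapError):
    """An input violates a size precondition (empty, too short, M > N...)."""


class TooShortError(SizeError):
    """A raw read is too short for event detection."""


class InsufficientEventsError(SizeError):
    """A read produced fewer events than adapter trim + query size."""


class ConfigError(SquigmapError):
    """Mismatched or invalid configuration (e.g. query/index fixed-point mismatch)."""
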