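"""Exception hierarchy for the dnapalette package."""


class DnaPaletteError(Exception):
    """Base class for all dnapalette errors."""


class InvalidSequenceError(DnaPaletteError, ValueError):
    """A sequence contains symbols outside {A, T, G, C} or has a wrong length."""


class NotFoundError(DnaPaletteError, KeyError):
    """An oligo is not a member of the universe it was looked up in."""


class RangeError(DnaPaletteError, IndexError):
    """A rank/index is outside the valid range of its universe or subset family."""


class CapacityError(DnaPaletteError, ValueError):
    """The message does not fit the universe / label space / address space."""


class InconsistentSubsetError(DnaPaletteError, ValueError):
    """A decoded subset has a rank >= 2**N, signalling a spurious oligo."""


class EncodingError(DnaPaletteError, RuntimeError):
    """Systematic syndrome forcing failed (should not happen with validated params)."""


class ConfigError(DnaPaletteError, ValueError):
    """A codec configuration or manifest is internally inconsistent."""


class ParseError(DnaPaletteError, ValueError):
    """A FASTA/FASTQ/manifest file is malformed."""
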