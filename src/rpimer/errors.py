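"""Structured exceptions raised across the package."""


class RpimerError(Exception):
    """Base class for all package-specific errors."""


class DotBracketError(RpimerError):
    """Malformed dot-bracket structure (unbalanced, crossing, or bad symbol).

    Attributes
    ----------
    position : int or None
        1-based offending position, or None when the defect is at end of
        string (e.g. an unmatched opening bracket).
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class AlphabetError(RpimerError):
    """A string contains symbols outside its representation's alphabet."""

    def __init__(self, message: str, string_id: str | None = None):
        super().__init__(message)
        self.string_id = string_id


class LengthMismatchError(RpimerError):
    """Two per-position strings that must align have different lengths."""


class SchemaError(RpimerError):
    """A feature vector/matrix has an unexpected block size or schema."""


class LabelError(RpimerError):
    """Invalid class labels (unknown token, single class, infeasible folds)."""


class FastaError(RpimerError):
    """Malformed FASTA input."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigError(RpimerError):
    """Invalid configuration value."""


class MotifError(RpimerError):
    """A planted motif cannot fit in the sequences it targets."""
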