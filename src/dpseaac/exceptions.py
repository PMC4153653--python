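"""Exception types shared across the package."""


class DPseAACError(Exception):
    """Base class for all package errors."""


class FastaFormatError(DPseAACError):
    """Raised when a FASTA file cannot be parsed."""


class ProfileError(DPseAACError):
    """Raised when a reduced-alphabet profile is not a valid partition
    of the 20 standard amino acids."""


class EncodingError(DPseAACError):
    """Raised when a sequence cannot be encoded (unknown residue, bad
    arguments, dimension mismatch)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        #: 1-based sequence position of the offending residue, if any
        self.position = position


class TrainingError(DPseAACError):
    """Raised when classifier training is impossible (e.g. one class)."""


class ModelLoadError(DPseAACError):
    """Raised when a persisted model file is corrupt or incompatible."""
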