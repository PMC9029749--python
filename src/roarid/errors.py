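"""Exception hierarchy shared across the pipeline."""


class RoarIdError(Exception):
    """Base class for all package errors."""


class UnsupportedFormatError(RoarIdError):
    """Audio file exists but is not PCM WAV (or uses an unsupported encoding)."""


class EmptyAudioError(RoarIdError):
    """WAV file contains a zero-length data chunk."""


class ShortSignalError(RoarIdError):
    """Signal too short for the requested transform or filter."""


class DegenerateFoldError(RoarIdError):
    """A cross-validation fold would leave a class absent from training."""


class AlignmentError(RoarIdError):
    """Score matrices disagree on sample ordering or class labels."""


class BackboneUnavailableError(RoarIdError):
    """A pretrained backbone plug-in cannot be resolved in this environment."""
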