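"""PCM WAV input/output and anti-aliased decimation.

Audio enters the pipeline as mono floating-point waveforms normalised to
[-1, 1].  The study's field recordings were 8-bit/16 kHz single-microphone
PCM, so the reader accepts low bit depths and averages any multichannel
input down to mono.  Decimation (used by the Stockwell path, factor 10 by
default) applies a zero-phase low-pass before subsampling so the decimated
images are free of aliased energy.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .errors import EmptyAudioError, ShortSignalError, UnsupportedFormatError

logger = logging.getLogger(__name__)

__all__ = ["AudioClip", "read_wav", "write_wav", "decimate"]


@dataclass
class AudioClip:
    """A mono waveform with amplitudes in [-1, 1].

    Parameters
    ----------
    samples : ndarray of float
        1-D waveform, peak absolute amplitude at most 1 after loading.
    sample_rate_hz : int
        Sampling rate in Hz, strictly positive.
    source_id : str, optional
        Free-text provenance label (file stem, synthetic sample id, ...).
    """

    samples: np.ndarray
    sample_rate_hz: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


# Full-scale constants per container dtype; integers are rescaled by the
# bit-depth maximum so that digital full scale maps to +/-1.0.
_INT_SCALE = {
    np.dtype(np.int16): 32767.0,
    np.dtype(np.int32): 2147483647.0,
}


def read_wav(path: str | os.PathLike) -> AudioClip:
    """Read a RIFF/WAVE PCM file into a normalised mono :class:`AudioClip`.

    Integer samples are rescaled to [-1, 1] by the bit-depth maximum
    (8-bit unsigned data is offset-binary decoded by subtracting 128);
    multichannel input is averaged to mono; the sample rate is preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedFormatError(
            f"{path}: not an uncompressed PCM WAV file ({exc})"
        ) from exc
    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length data chunk")

    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 127.0
    elif data.dtype in _INT_SCALE:
        x = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:  # pragma: no cover - scipy only emits the dtypes above
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return AudioClip(np.clip(x, -1.0, 1.0), int(rate), source_id=str(path))


def write_wav(clip: AudioClip, path: str | os.PathLike, bit_depth: int = 16):
    """Write ``clip`` as PCM WAV at 8 or 16 bits; returns ``path``.

    Amplitudes outside [-1, 1] are clipped with a logged warning rather
    than wrapped, so a slightly hot synthetic clip cannot corrupt a file.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    x = np.asarray(clip.samples, dtype=np.float64)
    if x.size and np.max(np.abs(x)) > 1.0:
        logger.warning("write_wav: clipping %s samples outside [-1, 1]",
                       int(np.sum(np.abs(x) > 1.0)))
        x = np.clip(x, -1.0, 1.0)
    if bit_depth == 16:
        data = np.round(x * 32767.0).astype(np.int16)
    else:  # 8-bit WAV is unsigned offset-binary per RIFF convention
        data = (np.round(x * 127.0) + 128.0).astype(np.uint8)
    wavfile.write(path, int(clip.sample_rate_hz), data)
    return path


def decimate(clip: AudioClip, factor: int) -> AudioClip:
    """Reduce the sample rate by an integer ``factor``.

    A zero-phase (forward-backward) order-8 Butterworth low-pass with
    cutoff 0.8x the new Nyquist is applied before subsampling; output
    length is ``floor(n / factor)`` and the rate divides exactly.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return AudioClip(clip.samples.copy(), clip.sample_rate_hz, clip.source_id)
    n = len(clip)
    if n < factor:
        raise ShortSignalError(f"clip of {n} samples cannot be decimated by {factor}")
    if clip.sample_rate_hz % factor:
        raise ValueError(
            f"sample rate {clip.sample_rate_hz} not divisible by factor {factor}"
        )
    sos = butter(8, 0.8 / factor, output="sos")
    # sosfiltfilt pads by reflection; it needs more than padlen samples.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if n <= padlen:
        raise ShortSignalError(
            f"clip of {n} samples is shorter than the filter warm-up ({padlen + 1})"
        )
    y = sosfiltfilt(sos, clip.samples)
    out = y[: (n // factor) * factor : factor]
    return AudioClip(out, clip.sample_rate_hz // factor, clip.source_id)
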