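"""Time-frequency image representations of roars.

Eight image-like renderings of a clip are supported: power spectrogram,
Mel spectrogram, the redesigned LM / L2M / L3M iterated-log features,
MFCC (inverse-transform convention, see :func:`compute_mfcc`), the
decimated Stockwell transform, and a 128-dimensional embedding-over-time
image.  Three post-hoc scaling modes (min-max to [0, 255], dB, box
normalisation to [0, C]) are composable with any representation.

Conventions that matter for exactness
-------------------------------------
* Frames are taken without padding or centering: a clip of n samples at
  window W and hop H yields 1 + floor((n - W)/H) columns.
* Every logarithm is floored at ``log_floor`` (default 1e-16, the same
  constant the dB scaling uses), so all images are finite by
  construction: the iterated-log chain's min-reference subtraction lands
  exactly on zero somewhere, where an unfloored log10 diverges.
* The Stockwell image is the one-sided magnitude with the zero-frequency
  voice (the running mean) dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import fft, ifft, rfft
from scipy.signal import get_window

from .audio_io import AudioClip, decimate
from .errors import ShortSignalError

logger = logging.getLogger(__name__)

__all__ = [
    "TimeFrequencyImage",
    "RepresentationConfig",
    "REPRESENTATIONS",
    "SCALING_MODES",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "compute_spectrogram",
    "compute_mel_spectrogram",
    "compute_lm",
    "compute_l2m",
    "compute_l3m",
    "compute_mfcc",
    "compute_stockwell",
    "compute_embedding_image",
    "StubEmbedder",
    "apply_scaling",
    "to_network_image",
    "extract_representation",
]

REPRESENTATIONS = ("spectrogram", "mel", "lm", "l2m", "l3m", "mfcc",
                   "stockwell", "embedding")
SCALING_MODES = ("min_max", "db", "box_n")

_ROW_AXIS = {
    "spectrogram": "linear_hz", "mel": "mel", "lm": "mel", "l2m": "mel",
    "l3m": "mel", "mfcc": "cepstral", "stockwell": "stockwell_hz",
    "embedding": "embedding",
}


@dataclass
class TimeFrequencyImage:
    """A 2-D real matrix: rows are frequency/coefficient bins, columns time frames."""

    values: np.ndarray
    representation: str
    row_axis: str
    scaling: str = "raw"
    scaling_constant: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("TimeFrequencyImage values must be 2-D")


@dataclass
class RepresentationConfig:
    """Shared analysis parameters.

    Defaults: 512-sample Hamming window (32 ms at 16 kHz, enough to
    resolve a ~200 Hz fundamental), hop 256, 512-point FFT, 32 Mel bands,
    13 cepstral coefficients, Stockwell decimation 10.
    """

    window_length: int = 512
    hop_length: int = 256
    fft_length: int = 512
    window_kind: str = "hamming"
    n_mel_bands: int = 32
    n_mfcc: int = 13
    log_floor: float = 1e-16
    stockwell_decimation: int = 10
    frequency_range_hz: tuple[float, float | None] = (0.0, None)

    def __post_init__(self) -> None:
        if not (self.hop_length <= self.window_length <= self.fft_length):
            raise ValueError("require hop_length <= window_length <= fft_length")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    def window(self) -> np.ndarray:
        if self.window_kind == "gaussian":
            return get_window(("gaussian", self.window_length / 6.0),
                              self.window_length, fftbins=True)
        return get_window(self.window_kind, self.window_length, fftbins=True)


# ---------------------------------------------------------------------------
# framing and the STFT power spectrogram
# ---------------------------------------------------------------------------

def _frames(x: np.ndarray, window_length: int, hop_length: int) -> np.ndarray:
    """(n_frames, window_length) view of x; no padding, no centering."""
    n = len(x)
    if n < window_length:
        raise ShortSignalError(
            f"clip of {n} samples is shorter than one window ({window_length})"
        )
    n_frames = 1 + (n - window_length) // hop_length
    idx = hop_length * np.arange(n_frames)[:, None] + np.arange(window_length)
    return x[idx]


def compute_spectrogram(clip: AudioClip, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """One-sided power spectrogram |STFT|^2.

    Rows = fft_length/2 + 1 bins, columns = 1 + floor((n - W)/H) frames.
    """
    frames = _frames(clip.samples, cfg.window_length, cfg.hop_length)
    spec = np.abs(rfft(frames * cfg.window(), n=cfg.fft_length, axis=1)) ** 2
    return TimeFrequencyImage(spec.T, "spectrogram", "linear_hz")


# ---------------------------------------------------------------------------
# Mel scale, filterbank, Mel spectrogram
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    """m = 2595 * log10(1 + f/700); strictly increasing."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(n_bands: int, fft_length: int, sample_rate_hz: int,
                   frequency_range_hz: tuple[float, float | None] = (0.0, None),
                   ) -> np.ndarray:
    """Triangular filters (peak 1) spaced uniformly on the Mel scale.

    Returns an (n_bands, fft_length//2 + 1) matrix acting on one-sided
    power spectra.
    """
    fmin, fmax = frequency_range_hz
    if fmax is None:
        fmax = sample_rate_hz / 2.0
    n_bins = fft_length // 2 + 1
    if n_bands > n_bins:
        raise ValueError(f"{n_bands} Mel bands exceed {n_bins} FFT bins")
    if n_bands < 2:
        raise ValueError("need at least 2 Mel bands")
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_bands + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_bins) * sample_rate_hz / fft_length
    fb = np.zeros((n_bands, n_bins))
    for b in range(n_bands):
        lo, ctr, hi = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return fb


def band_center_hz(band: int, cfg: RepresentationConfig, sample_rate_hz: int) -> float:
    """Center frequency of Mel band ``band`` under ``cfg`` (helper for tests/plots)."""
    fmin, fmax = cfg.frequency_range_hz
    if fmax is None:
        fmax = sample_rate_hz / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), cfg.n_mel_bands + 2)
    return mel_to_hz(mel_pts[band + 1])


def compute_mel_spectrogram(clip: AudioClip, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """Mel-filterbank projection of the power spectrogram; rows = n_mel_bands."""
    spec = compute_spectrogram(clip, cfg)
    fb = mel_filterbank(cfg.n_mel_bands, cfg.fft_length, clip.sample_rate_hz,
                        cfg.frequency_range_hz)
    return TimeFrequencyImage(fb @ spec.values, "mel", "mel")


# ---------------------------------------------------------------------------
# the iterated-log LM / L2M / L3M chain
# ---------------------------------------------------------------------------

def compute_lm(mel_image: TimeFrequencyImage, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """LM = 100 * log10(S) of the Mel spectrogram S, floored for finiteness."""
    if mel_image.representation != "mel":
        raise ValueError("compute_lm expects a Mel spectrogram")
    if np.any(mel_image.values < 0):
        raise ValueError("Mel spectrogram must be non-negative")
    out = 100.0 * np.log10(np.maximum(mel_image.values, cfg.log_floor))
    return TimeFrequencyImage(out, "lm", "mel")


def _iterated_log(values: np.ndarray, log_floor: float) -> np.ndarray:
    # minref subtraction shifts the matrix to start at 0; the floor keeps
    # the log finite exactly at the minimum.
    shifted = values - values.min()
    return 100.0 * np.log10(np.maximum(shifted, log_floor))


def compute_l2m(lm_image: TimeFrequencyImage, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """L2M = 100 * log10(LM - minref), minref the global minimum of LM."""
    if lm_image.representation != "lm":
        raise ValueError("compute_l2m expects an LM image")
    return TimeFrequencyImage(_iterated_log(lm_image.values, cfg.log_floor),
                              "l2m", "mel")


def compute_l3m(l2m_image: TimeFrequencyImage, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """L3M = 100 * log10(L2M - minref), the third iteration of the chain."""
    if l2m_image.representation != "l2m":
        raise ValueError("compute_l3m expects an L2M image")
    return TimeFrequencyImage(_iterated_log(l2m_image.values, cfg.log_floor),
                              "l3m", "mel")


# ---------------------------------------------------------------------------
# MFCC (inverse-Fourier convention)
# ---------------------------------------------------------------------------

def compute_mfcc(clip: AudioClip, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """Per frame: |F^-1(log(mel(|F(frame)|^2) + floor))|^2, first n_mfcc kept.

    Note this is the inverse-DFT reading of the cepstrum (magnitude
    squared of the inverse transform of the log Mel power spectrum), not
    the more common DCT-II convention.
    """
    if cfg.n_mfcc > cfg.n_mel_bands:
        raise ValueError("n_mfcc cannot exceed n_mel_bands")
    mel_img = compute_mel_spectrogram(clip, cfg)
    log_mel = np.log(mel_img.values + cfg.log_floor)
    ceps = np.abs(ifft(log_mel, axis=0)) ** 2
    return TimeFrequencyImage(ceps[: cfg.n_mfcc], "mfcc", "cepstral")


# ---------------------------------------------------------------------------
# decimated Stockwell transform
# ---------------------------------------------------------------------------

def compute_stockwell(clip: AudioClip, cfg: RepresentationConfig) -> TimeFrequencyImage:
    """One-sided Stockwell magnitude of the decimated clip.

    The input is decimated by ``cfg.stockwell_decimation`` (the transform
    is O(N^2 log N); decimation keeps it tractable), then the fast
    frequency-domain form is evaluated: for voice n, the inverse DFT over
    m of X[m + n] * exp(-2 pi^2 m^2 / n^2) with m the signed frequency
    index.  Rows are voices 1..N//2 (DC dropped), columns all N times.
    """
    dec = decimate(clip, cfg.stockwell_decimation)
    x = dec.samples
    n_samp = len(x)
    if n_samp < 8:
        raise ShortSignalError("decimated signal shorter than 8 samples")
    spec = fft(x) / n_samp
    m = np.fft.fftfreq(n_samp, d=1.0 / n_samp)  # signed frequency index
    voices = np.arange(1, n_samp // 2 + 1)
    out = np.empty((len(voices), n_samp))
    for i, v in enumerate(voices):
        gauss = np.exp(-2.0 * np.pi**2 * m**2 / v**2)
        out[i] = np.abs(ifft(np.roll(spec, -v) * gauss)) * n_samp
    return TimeFrequencyImage(out, "stockwell", "stockwell_hz")


# ---------------------------------------------------------------------------
# embedding-over-time image
# ---------------------------------------------------------------------------

class StubEmbedder:
    """Deterministic test embedder: fixed random projection of a window's
    log-Mel spectrum onto 128 dimensions.

    Satisfies the audio-embedding contract (``window_samples`` attribute
    plus ``embed(window, sample_rate_hz) -> (128,) vector``) without any
    pretrained network; a production embedder (e.g. a VGGish-style model)
    plugs in through the same contract.
    """

    n_features = 128

    def __init__(self, sample_rate_hz: int, window_s: float = 0.25, seed: int = 12345):
        self.sample_rate_hz = sample_rate_hz
        self.window_samples = int(round(window_s * sample_rate_hz))
        self._cfg = RepresentationConfig(
            window_length=min(256, self.window_samples),
            hop_length=min(128, self.window_samples),
            fft_length=256,
            n_mel_bands=32,
        )
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((self.n_features, self._cfg.n_mel_bands))

    def embed(self, window: np.ndarray, sample_rate_hz: int) -> np.ndarray:
        clip = AudioClip(window, sample_rate_hz)
        mel_img = compute_mel_spectrogram(clip, self._cfg)
        log_mel = np.log10(mel_img.values + 1e-10).mean(axis=1)
        return self._proj @ log_mel


def compute_embedding_image(clip: AudioClip, embedder) -> TimeFrequencyImage:
    """Stack consecutive non-overlapping window embeddings into a 128 x k image."""
    w = embedder.window_samples
    n_windows = len(clip) // w
    if n_windows < 1:
        raise ShortSignalError(
            f"clip of {len(clip)} samples shorter than one embedder window ({w})"
        )
    cols = [embedder.embed(clip.samples[i * w : (i + 1) * w], clip.sample_rate_hz)
            for i in range(n_windows)]
    return TimeFrequencyImage(np.stack(cols, axis=1), "embedding", "embedding")


# ---------------------------------------------------------------------------
# scaling modes and network-image conversion
# ---------------------------------------------------------------------------

def apply_scaling(img: TimeFrequencyImage, mode: str, constant: float = 1000.0,
                  ) -> TimeFrequencyImage:
    """Apply one of the three post-hoc scalings.

    min_max: (x - min)/(max - min) * 255;
    db:      10 * log10(x + 1e-16), defined for non-negative inputs;
    box_n:   (x - min)/(max - min) * constant (constant 1000 reproduces
             the [0-1000] Mel normalisation).
    A constant matrix under min_max/box_n maps to all-zeros (the formula
    divides by zero) with a logged warning.
    """
    x = img.values
    if mode == "db":
        if np.any(x < 0):
            raise ValueError("db scaling requires non-negative values")
        out = 10.0 * np.log10(x + 1e-16)
        const = float("nan")
    elif mode in ("min_max", "box_n"):
        top = 255.0 if mode == "min_max" else float(constant)
        if mode == "box_n" and constant <= 0:
            raise ValueError("box_n constant must be positive")
        span = x.max() - x.min()
        if span == 0:
            logger.warning("apply_scaling(%s): constant input mapped to zeros", mode)
            out = np.zeros_like(x)
        else:
            out = (x - x.min()) / span * top
        const = top
    else:
        raise ValueError(f"unknown scaling mode {mode!r}; use one of {SCALING_MODES}")
    return TimeFrequencyImage(out, img.representation, img.row_axis,
                              scaling=mode, scaling_constant=const)


def _bilinear_resize(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resampling at pixel centers (align-corners=False).

    At an exact 2x downsize every output pixel is the mean of its 2x2 block.
    """
    def axis_weights(n_in: int, n_out: int):
        pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        pos = np.clip(pos, 0, n_in - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = pos - lo
        return lo, hi, frac

    r_lo, r_hi, r_f = axis_weights(x.shape[0], out_h)
    c_lo, c_hi, c_f = axis_weights(x.shape[1], out_w)
    rows = x[r_lo] * (1 - r_f)[:, None] + x[r_hi] * r_f[:, None]
    return rows[:, c_lo] * (1 - c_f) + rows[:, c_hi] * c_f


def to_network_image(img: TimeFrequencyImage, target_height: int, target_width: int,
                     ) -> np.ndarray:
    """Affine-rescale to [0, 255], bilinear-resize, replicate to 3 channels.

    Returns an (target_height, target_width, 3) float array.  A constant
    (degenerate) input maps to mid-gray 127.5 with a logged warning.
    """
    x = img.values
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("image must have at least 2 rows and 2 columns")
    span = x.max() - x.min()
    if span == 0:
        logger.warning("to_network_image: constant input mapped to mid-gray")
        scaled = np.full_like(x, 127.5)
    else:
        scaled = (x - x.min()) / span * 255.0
    resized = _bilinear_resize(scaled, target_height, target_width)
    return np.repeat(resized[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def extract_representation(clip: AudioClip, name: str,
                           cfg: RepresentationConfig | None = None,
                           embedder=None) -> TimeFrequencyImage:
    """Compute any of the eight representations by name (unscaled)."""
    cfg = cfg or RepresentationConfig()
    if name == "spectrogram":
        return compute_spectrogram(clip, cfg)
    if name == "mel":
        return compute_mel_spectrogram(clip, cfg)
    if name in ("lm", "l2m", "l3m"):
        img = compute_lm(compute_mel_spectrogram(clip, cfg), cfg)
        if name in ("l2m", "l3m"):
            img = compute_l2m(img, cfg)
        if name == "l3m":
            img = compute_l3m(img, cfg)
        return img
    if name == "mfcc":
        return compute_mfcc(clip, cfg)
    if name == "stockwell":
        return compute_stockwell(clip, cfg)
    if name == "embedding":
        if embedder is None:
            embedder = StubEmbedder(clip.sample_rate_hz)
        return compute_embedding_image(clip, embedder)
    raise ValueError(
        f"unknown representation {name!r}; valid names: {', '.join(REPRESENTATIONS)}"
    )
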