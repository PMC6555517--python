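"""Multiresolution spectro-temporal auditory front-end.

Audio is analysed every 8 ms with five FFT windows of increasing length
(8-128 ms), trading temporal for spectral resolution across rows.  Each
power spectrum passes through a 128-filter triangular mel bank, and each
mel row is convolved along the tonotopic (filter-index) axis with a complex
kernel whose real part is a Mexican-hat (Ricker) wavelet and whose
imaginary part is its Hilbert transform — a coarse model of the symmetric /
antisymmetric spectral receptive fields of primary auditory cortex.  The
modulus of the convolution is normalized per frame (automatic gain
control), so the output carries spectral shape, not absolute level.

The output is a stream of 5 x 128 frames with values in [0, 1], plus an
"undetermined" mask marking elements whose pre-normalization magnitude is
negligible (digital silence or deep spectral nulls); the encoder imputes
those stochastically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.signal

__all__ = [
    "FrontEndConfig",
    "FrameStream",
    "ricker_kernel",
    "complex_cortical_kernel",
    "mel_filterbank",
    "multiresolution_power_spectra",
    "apply_mel_bank",
    "cortical_convolve",
    "magnitude_normalize",
    "process_audio",
    "process_wav_file",
    "save_frames",
    "load_frames",
]


@dataclass(frozen=True)
class FrontEndConfig:
    sample_rate: int = 16000
    frame_period: float = 0.008  # s between frames
    window_lengths: tuple[float, ...] = (0.008, 0.016, 0.032, 0.064, 0.128)
    n_filters: int = 128
    n_fft: int = 2048  # shared zero-padded FFT grid for all windows
    # Mexican-hat width (std dev, in filter-index units) per resolution
    coefficients: tuple[float, ...] = (10.0, 8.0, 6.0, 4.0, 2.0)
    mel_fmin: float = 0.0
    mel_fmax: float | None = None  # None -> Nyquist
    silence_epsilon: float = 1e-5  # relative to the stream's max magnitude
    normalize_per_row: bool = False  # gain control per resolution row

    def __post_init__(self):
        if len(self.coefficients) != len(self.window_lengths):
            raise ValueError("one convolution coefficient per window length")
        if any(w < self.frame_period for w in self.window_lengths):
            raise ValueError("window lengths must be >= frame period")
        if self.n_filters < 1:
            raise ValueError("need at least one mel filter")
        if self.sample_rate < 2000:
            raise ValueError("sample rate too low to resolve the mel range")
        if self.n_fft < max(self.window_samples):
            raise ValueError("n_fft must cover the longest window")

    @property
    def n_resolutions(self) -> int:
        return len(self.window_lengths)

    @property
    def hop(self) -> int:
        return int(round(self.frame_period * self.sample_rate))

    @property
    def window_samples(self) -> tuple[int, ...]:
        return tuple(int(round(w * self.sample_rate)) for w in self.window_lengths)


@dataclass
class FrameStream:
    """A sequence of front-end frames: (T, resolutions, filters) in [0, 1]."""

    values: np.ndarray  # float64 (T, R, F)
    undetermined: np.ndarray  # bool (T, R, F)
    times: np.ndarray  # float64 (T,) frame-end times in s
    config: FrontEndConfig

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def frame_undetermined(self) -> np.ndarray:
        """Frames in which every element is undetermined (silence)."""
        return self.undetermined.all(axis=(1, 2))


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, sample_rate: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filters: matrix (n_filters, n_fft//2 + 1)."""
    if n_filters < 1:
        raise ValueError("need at least one mel filter")
    if fmax is None:
        fmax = sample_rate / 2.0
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    edges = _mel_to_hz(mels)
    bins = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    bank = np.zeros((n_filters, len(bins)))
    for k in range(n_filters):
        lo, mid, hi = edges[k], edges[k + 1], edges[k + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        bank[k] = np.maximum(0.0, np.minimum(up, down))
    return bank


def mel_center_frequencies(
    n_filters: int, sample_rate: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    if fmax is None:
        fmax = sample_rate / 2.0
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    return _mel_to_hz(mels)[1:-1]


def ricker_kernel(c: float) -> np.ndarray:
    """Mexican-hat wavelet with standard deviation ``c``, truncated at +/-4c.

    The samples are demeaned so the discrete kernel sums exactly to zero
    (the defining property of the Mexican hat: no DC response).
    """
    if c <= 0:
        raise ValueError("kernel width must be positive")
    half = int(np.ceil(4.0 * c))
    x = np.arange(-half, half + 1, dtype=float)
    a = 2.0 / (np.sqrt(3.0 * c) * np.pi**0.25)
    k = a * (1.0 - (x / c) ** 2) * np.exp(-(x**2) / (2.0 * c**2))
    return k - k.mean()


def complex_cortical_kernel(c: float) -> np.ndarray:
    """Analytic kernel: Ricker real part + its Hilbert transform imaginary part."""
    real = ricker_kernel(c)
    return scipy.signal.hilbert(real)


def multiresolution_power_spectra(
    audio: np.ndarray, config: FrontEndConfig
) -> list[np.ndarray]:
    """Per-resolution power spectra, one row per 8 ms frame.

    Resolution r uses a Hann window of length w_r ending at the frame time;
    the head of the signal is zero-padded so the first frame exists.  All
    windows share the zero-padded ``n_fft`` frequency grid, so spectral
    resolution still comes from the window length while every resolution
    maps onto one mel bank.  Returns a list of (n_frames, n_fft//2+1) arrays.
    """
    audio = np.asarray(audio, dtype=float)
    hop = config.hop
    n_frames = len(audio) // hop
    max_w = max(config.window_samples)
    padded = np.concatenate([np.zeros(max_w), audio])
    out = []
    for w in config.window_samples:
        ends = max_w + hop * (np.arange(n_frames) + 1)
        idx = ends[:, None] - w + np.arange(w)[None, :]
        frames = padded[idx] * np.hanning(w)[None, :]
        spec = np.abs(np.fft.rfft(frames, n=config.n_fft, axis=1)) ** 2 / w
        out.append(spec)
    return out


def apply_mel_bank(spectrum: np.ndarray, config: FrontEndConfig) -> np.ndarray:
    """Project power-spectrum rows (on the n_fft grid) onto the mel filters."""
    bank = mel_filterbank(
        config.n_filters, config.n_fft, config.sample_rate, config.mel_fmin, config.mel_fmax
    )
    return np.atleast_2d(spectrum) @ bank.T


def cortical_convolve(mel_rows: np.ndarray, coefficient: float) -> np.ndarray:
    """Convolve mel rows along the filter axis with the complex cortical kernel.

    Reflect padding avoids edge artifacts.  Accepts (..., n_filters) and
    returns complex output of the same shape.
    """
    kernel = complex_cortical_kernel(coefficient)
    half = (len(kernel) - 1) // 2
    rows = np.atleast_2d(mel_rows)
    if half > rows.shape[-1] - 1:
        raise ValueError("cortical kernel wider than the tonotopic axis")
    padded = np.pad(rows, [(0, 0)] * (rows.ndim - 1) + [(half, half)], mode="reflect")
    out = scipy.signal.fftconvolve(padded, kernel[None, :], mode="valid", axes=-1)
    return out.reshape(np.shape(mel_rows))


def magnitude_normalize(
    frames_complex: np.ndarray, per_row: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Take the modulus and apply per-frame automatic gain control.

    frames_complex: (T, R, F) complex.  Returns (values, pre_norm_magnitude);
    values are scaled so each frame's max is exactly 1 (all-zero frames stay
    zero).  With per_row=True the gain control acts per resolution row.
    """
    frames_complex = np.asarray(frames_complex)
    squeeze = frames_complex.ndim == 2  # a single (R, F) frame
    if squeeze:
        frames_complex = frames_complex[None]
    mag = np.abs(frames_complex)
    axis = (2,) if per_row else (1, 2)
    peak = mag.max(axis=axis, keepdims=True)
    values = np.divide(mag, peak, out=np.zeros_like(mag), where=peak > 0)
    if squeeze:
        return values[0], mag[0]
    return values, mag


def process_audio(audio: np.ndarray, config: FrontEndConfig | None = None) -> FrameStream:
    """Run the full front-end chain on a mono signal.

    The signal is peak-normalized first so the stream (including the
    silence/undetermined mask) is invariant to global input gain.
    """
    config = config or FrontEndConfig()
    audio = np.asarray(audio, dtype=float)
    peak = np.max(np.abs(audio)) if len(audio) else 0.0
    if peak > 0:
        audio = audio / peak
    spectra = multiresolution_power_spectra(audio, config)
    n_frames = spectra[0].shape[0] if spectra else 0
    stack = np.zeros((n_frames, config.n_resolutions, config.n_filters), dtype=complex)
    for r in range(config.n_resolutions):
        mel = apply_mel_bank(spectra[r], config)
        stack[:, r, :] = cortical_convolve(mel, config.coefficients[r])
    values, prenorm = magnitude_normalize(stack, per_row=config.normalize_per_row)
    global_max = prenorm.max() if prenorm.size else 0.0
    undet = prenorm <= config.silence_epsilon * max(global_max, np.finfo(float).tiny)
    times = config.frame_period * (np.arange(n_frames) + 1)
    return FrameStream(values=values, undetermined=undet, times=times, config=config)


def process_wav_file(path: str | Path, config: FrontEndConfig | None = None) -> FrameStream:
    from scipy.io import wavfile

    sr, audio = wavfile.read(path)
    if audio.ndim > 1:
        audio = audio.mean(axis=1)
    if np.issubdtype(audio.dtype, np.integer):
        audio = audio / float(np.iinfo(audio.dtype).max)
    config = config or FrontEndConfig()
    if sr != config.sample_rate:
        config = FrontEndConfig(**{**config.__dict__, "sample_rate": int(sr)})
    return process_audio(audio, config)


def save_frames(path: str | Path, stream: FrameStream) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=stream.values, compression="gzip")
        fh.create_dataset("undetermined", data=stream.undetermined, compression="gzip")
        fh.create_dataset("times", data=stream.times)
        fh.attrs["config"] = json.dumps(stream.config.__dict__)


def load_frames(path: str | Path) -> FrameStream:
    with h5py.File(path, "r") as fh:
        cfg = json.loads(fh.attrs["config"])
        cfg["window_lengths"] = tuple(cfg["window_lengths"])
        cfg["coefficients"] = tuple(cfg["coefficients"])
        return FrameStream(
            values=fh["values"][...],
            undetermined=fh["undetermined"][...],
            times=fh["times"][...],
            config=FrontEndConfig(**cfg),
        )
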