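"""Continuous wavelet transform scalograms of one-minute ECG segments.

The analyzing wavelet is the complex Morlet

    phi(t) = (1/sqrt(b*pi)) * exp(-t^2/b) * exp(j*2*pi*Fc*t)

with bandwidth ``b`` (default 1.5) and center frequency ``Fc`` (default 1.0).
The transform of a sampled signal x[n] at scale ``s`` (in samples) and
translation ``tau`` is the discretized correlation

    C(s, tau) = (1/sqrt(s)) * sum_n x[n] * conj(phi((n - tau)/s)) * dt

with ``dt = 1/fs`` and zero-padded edges, so each scale row has the same
length as the segment.  A scale maps to an analysis frequency via
``F = Fc * fs / s``; the default grid is 128 log-spaced scales spanning
0.5-40 Hz, i.e. the band the preprocessing retains.

The scalogram image is |C| min-max normalized, colormapped, and bilinearly
resized to 224x224 with low frequencies at the bottom of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .ecg_io import EncodedImage
from .errors import ValidationError
from .rendering import DEFAULT_COLORMAP, apply_colormap, resize_bilinear

#: truncate the Gaussian envelope where exp(-u^2/b) < ~1e-8
_ENVELOPE_CUT = 4.3


@dataclass
class WaveletParams:
    """Morlet bandwidth ``b`` (dimensionless) and center frequency ``Fc``."""

    b: float = 1.5
    fc: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.fc <= 0:
            raise ValidationError("Morlet parameters b and Fc must be positive")


@dataclass
class CoefficientMatrix:
    """Complex CWT coefficients indexed (scale, translation)."""

    values: np.ndarray
    scales: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.scales):
            raise ValidationError("coefficient matrix must be (n_scales, n_samples)")
        if np.any(self.scales <= 0) or np.any(np.diff(self.scales) <= 0):
            raise ValidationError("scales must be positive and strictly increasing")


def morlet(t: np.ndarray | float, params: WaveletParams) -> np.ndarray | complex:
    """Evaluate the complex Morlet wavelet at time(s) ``t``."""
    t = np.asarray(t, dtype=np.float64)
    out = (1.0 / np.sqrt(params.b * np.pi)
           * np.exp(-(t ** 2) / params.b)
           * np.exp(2j * np.pi * params.fc * t))
    return out if out.ndim else complex(out)


def scale_to_freq(s: np.ndarray | float, params: WaveletParams,
                  fs: float) -> np.ndarray | float:
    """Convert a scale (in samples) to its analysis frequency ``Fc*fs/s``."""
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0):
        raise ValidationError("scale must be positive")
    f = params.fc * fs / s
    return f if f.ndim else float(f)


def freq_to_scale(f: np.ndarray | float, params: WaveletParams,
                  fs: float) -> np.ndarray | float:
    """Inverse of :func:`scale_to_freq`."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f <= 0):
        raise ValidationError("frequency must be positive")
    s = params.fc * fs / f
    return s if s.ndim else float(s)


def default_scales(fs: float, params: WaveletParams | None = None,
                   n_scales: int = 128, f_min_hz: float = 0.5,
                   f_max_hz: float = 40.0) -> np.ndarray:
    """Log-spaced scale grid whose mapped frequencies span [f_min, f_max]."""
    params = params or WaveletParams()
    if not (0 < f_min_hz < f_max_hz):
        raise ValidationError("need 0 < f_min < f_max")
    s_min = freq_to_scale(f_max_hz, params, fs)
    s_max = freq_to_scale(f_min_hz, params, fs)
    return np.geomspace(s_min, s_max, n_scales)


def cwt_transform(segment: np.ndarray, fs: float, scales: np.ndarray,
                  params: WaveletParams | None = None) -> CoefficientMatrix:
    """Compute CWT coefficients of ``segment`` at every sample shift.

    Each scale row is the correlation of the signal with the scaled wavelet,
    evaluated by FFT convolution with zero-padded edges.
    """
    params = params or WaveletParams()
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("segment must be a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("segment must be finite")
    scales = np.asarray(scales, dtype=np.float64)
    if scales.size == 0:
        raise ValidationError("scales must be non-empty")
    dt = 1.0 / fs
    rows = np.empty((scales.size, x.size), dtype=np.complex128)
    for i, s in enumerate(scales):
        half = int(np.ceil(_ENVELOPE_CUT * np.sqrt(params.b) * s))
        m = np.arange(-half, half + 1)
        # correlation with conj(phi((n-tau)/s)) == convolution with phi(m/s)
        kernel = morlet(m / s, params)
        rows[i] = fftconvolve(x, kernel, mode="same") * (dt / np.sqrt(s))
    return CoefficientMatrix(values=rows, scales=scales, fs=fs)


class CwtBank:
    """Precomputed wavelet filter bank for repeated same-length transforms.

    Computes exactly what :func:`cwt_transform` computes, but shares one
    padded FFT of the signal across all scales and caches the kernel FFTs,
    which is ~20x faster when encoding many segments of equal length.
    """

    def __init__(self, n_samples: int, fs: float, scales: np.ndarray,
                 params: WaveletParams | None = None):
        from scipy.fft import next_fast_len

        self.params = params or WaveletParams()
        self.fs = fs
        self.scales = np.asarray(scales, dtype=np.float64)
        if self.scales.size == 0:
            raise ValidationError("scales must be non-empty")
        self.n = n_samples
        halves = np.ceil(_ENVELOPE_CUT * np.sqrt(self.params.b)
                         * self.scales).astype(int)
        self.nfft = next_fast_len(n_samples + 2 * int(halves.max()))
        self._kernel_fft = np.empty((self.scales.size, self.nfft),
                                    dtype=np.complex128)
        self._offsets = np.empty(self.scales.size, dtype=int)
        for i, (s, half) in enumerate(zip(self.scales, halves)):
            m = np.arange(-half, half + 1)
            kernel = morlet(m / s, self.params)
            self._kernel_fft[i] = np.fft.fft(kernel, self.nfft)
            self._offsets[i] = half          # 'same' slice start for odd kernels

    def transform(self, segment: np.ndarray) -> CoefficientMatrix:
        x = np.asarray(segment, dtype=np.float64)
        if x.shape != (self.n,):
            raise ValidationError(f"bank expects length-{self.n} segments")
        xf = np.fft.fft(x, self.nfft)
        full = np.fft.ifft(self._kernel_fft * xf[None, :], axis=1)
        dt = 1.0 / self.fs
        rows = np.empty((self.scales.size, self.n), dtype=np.complex128)
        for i, off in enumerate(self._offsets):
            rows[i] = full[i, off:off + self.n]
        rows *= (dt / np.sqrt(self.scales))[:, None]
        return CoefficientMatrix(values=rows, scales=self.scales, fs=self.fs)


def render_scalogram(coeffs: CoefficientMatrix,
                     colormap: str = DEFAULT_COLORMAP,
                     source: tuple[str, int] = ("", 0),
                     label: str = "N") -> EncodedImage:
    """Render |C| as a 224x224 RGB image (low frequency at the bottom).

    Magnitudes are min-max normalized; a constant-magnitude matrix maps to
    the colormap midpoint everywhere.  The scale axis is stored ascending, so
    row 0 (image top) is the highest analysis frequency.
    """
    mag = np.abs(coeffs.values)
    if mag.size == 0:
        raise ValidationError("empty coefficient matrix")
    lo, hi = float(mag.min()), float(mag.max())
    u = np.full_like(mag, 0.5) if hi == lo else (mag - lo) / (hi - lo)
    rgb = apply_colormap(u, colormap)
    return EncodedImage(pixels=resize_bilinear(rgb).astype(np.float32),
                        modality="CWT", source=source, label=label)


def encode_segment(samples: np.ndarray, fs: float,
                   params: WaveletParams | None = None,
                   scales: np.ndarray | None = None,
                   colormap: str = DEFAULT_COLORMAP,
                   source: tuple[str, int] = ("", 0),
                   label: str = "N") -> EncodedImage:
    """One-call scalogram encoding of a preprocessed segment."""
    params = params or WaveletParams()
    if scales is None:
        scales = default_scales(fs, params)
    coeffs = cwt_transform(samples, fs, scales, params)
    return render_scalogram(coeffs, colormap=colormap, source=source, label=label)
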