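"""Complex Morlet wavelet time-frequency decomposition.

The default grid runs 2-18 Hz in 17 linearly spaced steps with the number
of cycles increasing logarithmically from 3 to 10, the standard choice for
low-frequency infant EEG.  Coefficients are scaled so that the magnitude
at a matched frequency recovers the amplitude of a sinusoid; their angle
is the instantaneous phase consumed by the synchrony statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "default_freqs",
    "default_cycles",
    "TFDecomposition",
    "morlet_decompose",
    "band_average",
    "THETA",
    "ALPHA",
]

#: Canonical infant-EEG bands (inclusive edges; 6 Hz belongs to both).
THETA = (3.0, 6.0)
ALPHA = (6.0, 9.0)


def default_freqs() -> np.ndarray:
    return np.linspace(2.0, 18.0, 17)


def default_cycles(n: int = 17) -> np.ndarray:
    return np.logspace(np.log10(3.0), np.log10(10.0), n)


@dataclass
class TFDecomposition:
    """Complex Morlet coefficients with shape (..., n_freqs, n_times).

    ``edge_valid[f, t]`` is False within half a wavelet length (4 sigma_t)
    of either boundary, where coefficients are contaminated by edge
    effects and should be excluded from statistics.
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    cycles: np.ndarray
    fs: float
    edge_valid: np.ndarray

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in (-pi, pi]."""
        return np.angle(self.coefficients)

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[-1]


def _morlet_kernel(freq: float, cycles: float, fs: float) -> np.ndarray:
    """Gaussian-windowed complex exponential, truncated at ±4 sigma_t.

    Scaled so that convolution with ``cos(2 pi f t)`` returns magnitude 1
    at the matched frequency (amplitude-preserving convention).
    """
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    # response of the kernel to a unit cosine at f is ~ (1/2) * sum(gauss)
    kernel *= 2.0 / np.exp(-(t**2) / (2 * sigma_t**2)).sum()
    return kernel


def morlet_decompose(data, fs: float, freqs=None, cycles=None) -> TFDecomposition:
    """Convolve ``data`` (..., n_times) with the Morlet family.

    Output coefficients have shape (..., n_freqs, n_times) (centred,
    same-length convolution).  Linear in the input.
    """
    data = np.asarray(data, dtype=float)
    freqs = default_freqs() if freqs is None else np.atleast_1d(np.asarray(freqs, float))
    cycles = default_cycles(len(freqs)) if cycles is None else np.atleast_1d(np.asarray(cycles, float))
    if len(cycles) != len(freqs):
        raise ValueError("freqs and cycles must have equal length")
    if np.any(freqs >= fs / 2):
        raise ValueError("all frequencies must be below Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    n_times = data.shape[-1]
    out = np.empty(data.shape[:-1] + (len(freqs), n_times), dtype=complex)
    edge_valid = np.zeros((len(freqs), n_times), dtype=bool)
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        kernel = _morlet_kernel(f, c, fs)
        shape = (1,) * (data.ndim - 1) + (len(kernel),)
        out[..., i, :] = fftconvolve(data, kernel.reshape(shape), mode="same", axes=-1)
        half = (len(kernel) - 1) // 2
        if n_times > 2 * half:
            edge_valid[i, half : n_times - half] = True
    return TFDecomposition(out, freqs, cycles, fs, edge_valid)


def band_average(values, freqs, band, axis=0):
    """Unweighted mean over grid frequencies inside ``band`` (inclusive)."""
    freqs = np.asarray(freqs, float)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    values = np.asarray(values)
    return np.take(values, np.flatnonzero(sel), axis=axis).mean(axis=axis)
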