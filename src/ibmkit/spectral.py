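"""Amplitude spectra, spectral peaks, BPM conversion, and spectrograms.

Whole-phase spectra use a plain (rectangular-window) FFT with a single-sided
amplitude convention: a unit sinusoid at a bin center yields amplitude 1 at
that bin, and a constant c yields |c| at DC. The cardiac peak of the
easy-phase spectrum converts directly to beats per minute (f * 60, rounded
to the nearest integer). Time-dependent frequency content is examined with a
Hann-windowed short-time Fourier transform magnitude (spectrogram).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
from scipy import signal as _signal

from .preprocess import UniformSeries


@dataclass(frozen=True)
class Spectrum:
    """Single-sided amplitude spectrum on the grid 0..Nyquist, spacing rate/n."""

    freqs: np.ndarray
    amps: np.ndarray
    n: int
    rate: float

    @property
    def bin_width(self) -> float:
        return self.rate / self.n


@dataclass(frozen=True)
class SpectralPeaks:
    """Peaks as (freq_hz, amplitude, prominence), sorted by amplitude descending."""

    peaks: Tuple[Tuple[float, float, float], ...]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def freqs(self) -> List[float]:
        return [p[0] for p in self.peaks]


@dataclass(frozen=True)
class TimeFreqMap:
    """Short-time Fourier magnitude: ``magnitude[i, j]`` at ``times[i]``, ``freqs[j]``."""

    times: np.ndarray
    freqs: np.ndarray
    magnitude: np.ndarray
    window_s: float
    overlap_fraction: float


def amplitude_spectrum(series: UniformSeries) -> Spectrum:
    """Single-sided amplitude spectrum of a uniform series.

    Scaling: interior bins carry 2|X_k|/n so a unit sinusoid at a bin center
    reads 1.0; the DC bin (and the Nyquist bin for even n) carries |X_k|/n.
    """
    n = len(series)
    if n < 2:
        raise ValueError(f"need at least 2 samples for a spectrum, got {n}")
    x = np.fft.rfft(series.values)
    amps = np.abs(x) / n
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / series.rate)
    return Spectrum(freqs=freqs, amps=amps, n=n, rate=series.rate)


def find_peaks(
    spec: Spectrum,
    band: Tuple[float, float],
    k: int = 3,
    min_prominence_fraction: float = 0.05,
) -> SpectralPeaks:
    """Up to ``k`` most prominent local maxima of the spectrum within ``band``.

    Peaks must have prominence at least ``min_prominence_fraction`` times the
    maximum in-band amplitude. Results are sorted by amplitude descending;
    amplitude ties break toward the lower frequency.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band must satisfy low < high, got {band}")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"band {band} contains no spectrum bins (grid spacing {spec.bin_width:g} Hz)")
    sub = spec.amps[idx]
    if sub.size < 3 or np.all(sub == sub[0]):
        return SpectralPeaks(peaks=())
    threshold = min_prominence_fraction * float(sub.max())
    locs, props = _signal.find_peaks(sub, prominence=threshold)
    entries = [
        (float(spec.freqs[idx[i]]), float(sub[i]), float(p))
        for i, p in zip(locs, props["prominences"])
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return SpectralPeaks(peaks=tuple(entries[:k]))


def hz_to_bpm(f: float) -> int:
    """Convert a spectral frequency to beats per minute.

    Rounds to the nearest integer, halves away from zero (2.090 Hz -> 125 BPM).
    """
    if f < 0:
        raise ValueError(f"frequency must be >= 0, got {f}")
    return int(math.floor(f * 60.0 + 0.5))


def spectrogram(
    series: UniformSeries, window_s: float = 10.0, overlap_fraction: float = 0.5
) -> TimeFreqMap:
    """Hann-windowed short-time Fourier magnitude.

    ``times`` are window centers in absolute series time (referenced to
    ``series.t0``).
    """
    nperseg = round(window_s * series.rate)
    if nperseg < 4:
        raise ValueError(f"window of {window_s} s spans fewer than 4 samples at {series.rate} Hz")
    if nperseg > len(series):
        raise ValueError(
            f"window of {window_s} s ({nperseg} samples) exceeds series length {len(series)}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    noverlap = int(overlap_fraction * nperseg)
    freqs, times, mag = _signal.spectrogram(
        series.values,
        fs=series.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        mode="magnitude",
        detrend=False,
    )
    return TimeFreqMap(
        times=times + series.t0,
        freqs=freqs,
        magnitude=mag.T,
        window_s=window_s,
        overlap_fraction=overlap_fraction,
    )
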