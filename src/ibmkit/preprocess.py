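"""Front half of the signal-conditioning pipeline.

A raw differential-acceleration recording is truncated to the start of the
breath hold, lowpass filtered with a zero-phase 12th-order Butterworth design
(50 Hz corner), decimated from the raw acquisition rate (~1000 Hz) to the
logging rate (100 Hz), and normalized against the easy-phase baseline:

    y_norm = (y_raw - mean(y_easy)) / max|y_raw - mean(y_easy)|

so that the output is dimensionless, zero-mean over the easy window, and has
at least one sample at +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class UniformSeries:
    """Uniformly sampled real-valued series.

    Parameters
    ----------
    values : ndarray
        Finite samples.
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds, measured from acquisition start.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds (0 for length <= 1)."""
        return max(len(self) - 1, 0) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds (t0 + i / rate)."""
        return self.t0 + np.arange(len(self)) / self.rate

    def replace(self, **kwargs) -> "UniformSeries":
        params = {"values": self.values, "rate": self.rate, "t0": self.t0}
        params.update(kwargs)
        return UniformSeries(**params)


@dataclass(frozen=True)
class EasyWindow:
    """Baseline window [start_s, end_s) in absolute series time."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"easy window must have start < end, got [{self.start_s}, {self.end_s})"
            )

    def indices(self, series: UniformSeries) -> np.ndarray:
        t = series.times
        mask = (t >= self.start_s) & (t < self.end_s)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(
                f"easy window [{self.start_s}, {self.end_s}) s contains no samples of a "
                f"series spanning [{series.t0}, {series.t0 + series.duration}] s"
            )
        return idx


@dataclass(frozen=True)
class NormalizedSeries(UniformSeries):
    """Baseline-normalized series; `values * scale + baseline_mean` recovers the input."""

    baseline_mean: float = 0.0
    scale: float = 1.0

    def replace(self, **kwargs):
        params = {
            "values": self.values,
            "rate": self.rate,
            "t0": self.t0,
            "baseline_mean": self.baseline_mean,
            "scale": self.scale,
        }
        params.update(kwargs)
        return NormalizedSeries(**params)

    def denormalize(self) -> UniformSeries:
        return UniformSeries(
            self.values * self.scale + self.baseline_mean, self.rate, self.t0
        )


def truncate_start(series: UniformSeries, t_start: float) -> UniformSeries:
    """Drop the first ``t_start`` seconds (e.g. sitting motion before the hold).

    ``t_start`` is relative to the start of the series. The output's ``t0`` is
    advanced accordingly so absolute timestamps are preserved.
    """
    if t_start < 0:
        raise ValueError(f"t_start must be >= 0, got {t_start}")
    n_drop = round(t_start * series.rate)
    if n_drop > len(series):
        raise ValueError(
            f"t_start={t_start} s is beyond the series end ({len(series) / series.rate} s)"
        )
    return series.replace(values=series.values[n_drop:], t0=series.t0 + n_drop / series.rate)


def _sos_lowpass(corner: float, order: int, rate: float) -> np.ndarray:
    # cascaded biquads: a 12th-order polynomial form is numerically unsafe
    return signal.butter(order, corner, btype="low", fs=rate, output="sos")


def lowpass_zero_phase(
    series: UniformSeries, corner: float = 50.0, order: int = 12
) -> UniformSeries:
    """Zero-phase lowpass Butterworth filter (forward-backward application).

    The filter is designed at ``order`` and applied in both directions, so the
    effective magnitude response is the squared Butterworth response and the
    net phase response is zero (no time shift of signal features).
    """
    nyq = series.rate / 2
    if not 0 < corner < nyq:
        raise ValueError(f"corner must lie in (0, Nyquist={nyq} Hz), got {corner}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    sos = _sos_lowpass(corner, order, series.rate)
    filtered = signal.sosfiltfilt(sos, series.values, padtype="even")
    return series.replace(values=filtered)


def decimate(series: UniformSeries, factor: int = 10) -> UniformSeries:
    """Keep every ``factor``-th sample (index 0 retained).

    The caller is responsible for band-limiting first (the pipeline applies
    the 50 Hz lowpass before decimating 1000 Hz -> 100 Hz).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    return series.replace(values=series.values[::factor], rate=series.rate / factor)


def normalize_easy(series: UniformSeries, easy: EasyWindow) -> NormalizedSeries:
    """Normalize against the easy-phase baseline.

    Subtracts the mean over the easy window, then divides by the maximum
    absolute deviation so the result lies in [-1, 1] with at least one sample
    at an extreme. The baseline mean and scale are retained for invertibility.
    """
    idx = easy.indices(series)
    baseline = float(np.mean(series.values[idx]))
    centered = series.values - baseline
    scale = float(np.max(np.abs(centered))) if centered.size else 0.0
    if scale == 0.0:
        raise ValueError(
            "cannot normalize: signal is constant and equal to the easy-window mean "
            "(zero maximum deviation)"
        )
    return NormalizedSeries(
        values=centered / scale,
        rate=series.rate,
        t0=series.t0,
        baseline_mean=baseline,
        scale=scale,
    )
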