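"""Back half of the pipeline: bandpass, envelope, phase landmarks, orchestration.

The normalized differential signal is bandpass filtered (zero-phase
Butterworth, 0.5-3.5 Hz, 5th order) to isolate cardiac and IBM content, then
squared so every involuntary breathing movement shows as a non-negative
energy burst. A long-window SSA trend of that envelope tracks the growth of
IBM magnitude across the struggle phase; a short moving-average envelope
feeds the breaking-point detector.

The physiological breaking point is the onset of the struggle phase: the
earliest time the detection envelope exceeds the easy-phase baseline mean by
``k`` baseline standard deviations continuously for a dwell time. The dwell
requirement rejects isolated artifacts such as single postural spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as _signal

from . import decompose as _decompose
from . import spectral as _spectral
from .logformat import DeviceLog, to_uniform_series
from .preprocess import (
    EasyWindow,
    NormalizedSeries,
    UniformSeries,
    decimate,
    lowpass_zero_phase,
    normalize_easy,
    truncate_start,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass(frozen=True)
class EnvelopeSignal(UniformSeries):
    """Squared band-limited signal: non-negative, dimensionless squared units."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self) and np.min(self.values) < 0:
            raise ValueError("envelope values must be non-negative")


@dataclass(frozen=True)
class BreathHoldPhases:
    """The breath-hold landmarks, in seconds from the start of the hold.

    ``t_physio_break`` is absent (None) when no struggle phase was detected.
    """

    t_hold_start: float
    t_physio_break: Optional[float]
    t_conv_break: Optional[float]

    def __post_init__(self) -> None:
        pts = [self.t_hold_start, self.t_physio_break, self.t_conv_break]
        pts = [p for p in pts if p is not None]
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"phase landmarks out of order: {pts}")

    @property
    def easy_span(self) -> Optional[Tuple[float, float]]:
        if self.t_physio_break is None:
            return None
        return (self.t_hold_start, self.t_physio_break)

    @property
    def struggle_span(self) -> Optional[Tuple[float, float]]:
        if self.t_physio_break is None or self.t_conv_break is None:
            return None
        return (self.t_physio_break, self.t_conv_break)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis pipeline.

    Times are in seconds from the start of acquisition unless noted. The
    easy-phase baseline window defaults to the first ``easy_baseline_s``
    seconds after ``hold_start_s``; it anchors both the normalization and the
    breaking-point threshold, so it must precede the first IBM.
    """

    hold_start_s: float = 0.0
    conv_break_s: Optional[float] = None  # end of record when None
    easy_baseline_s: float = 10.0
    lowpass_corner_hz: float = 50.0
    lowpass_order: int = 12
    target_rate_hz: float = 100.0
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 3.5
    bandpass_order: int = 5
    envelope_lowpass_hz: float = 4.0
    envelope_rate_hz: float = 10.0
    ssa_window_s: float = 20.0
    trend_cutoff_hz: float = 0.1
    energy_floor: float = 0.05
    detect_smooth_s: float = 2.0
    detect_k: float = 3.0
    detect_min_hold_s: float = 2.0
    spectrogram_window_s: float = 10.0
    spectrogram_overlap: float = 0.5
    peak_band_hz: Tuple[float, float] = (0.3, 3.5)
    peak_count: int = 3
    peak_min_prominence: float = 0.05


@dataclass
class AnalysisReport:
    """Everything the pipeline produced for one recording.

    All times in ``phases``, ``trend``, and ``spectrogram`` are referenced to
    the start of the breath hold (t = 0 at hold start).
    """

    phases: BreathHoldPhases
    easy_peaks: _spectral.SpectralPeaks
    struggle_peaks: _spectral.SpectralPeaks
    trend: UniformSeries
    spectrogram: Optional[_spectral.TimeFreqMap]
    provenance: Dict
    normalized: Optional[NormalizedSeries] = None
    easy_spectrum: Optional[_spectral.Spectrum] = None
    struggle_spectrum: Optional[_spectral.Spectrum] = None


def bandpass_zero_phase(
    series: UniformSeries, low: float = 0.5, high: float = 3.5, order: int = 5
) -> UniformSeries:
    """Zero-phase bandpass Butterworth filter (forward-backward application)."""
    nyq = series.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"corners must satisfy 0 < low < high < Nyquist={nyq} Hz, got ({low}, {high})"
        )
    sos = _signal.butter(order, [low, high], btype="band", fs=series.rate, output="sos")
    return series.replace(values=_signal.sosfiltfilt(sos, series.values, padtype="even"))


def square_signal(series: UniformSeries) -> EnvelopeSignal:
    """Element-wise square: all IBM deflections become non-negative energy."""
    return EnvelopeSignal(values=series.values**2, rate=series.rate, t0=series.t0)


def smooth_envelope(series: UniformSeries, width_s: float = 2.0) -> UniformSeries:
    """Centered moving-average of an envelope (boxcar of ``width_s`` seconds).

    Wide enough to bridge the gaps between successive IBM bursts so a
    sustained struggle phase stays above threshold.
    """
    width = max(round(width_s * series.rate), 1)
    kernel = np.ones(width) / width
    padded = np.pad(series.values, (width // 2, width - 1 - width // 2), mode="edge")
    return series.replace(values=np.convolve(padded, kernel, mode="valid"))


def detect_physio_break(
    trend: UniformSeries,
    easy_baseline: EasyWindow,
    k: float = 3.0,
    min_hold_s: float = 2.0,
) -> Optional[float]:
    """Earliest sustained excursion of a trend above its easy-phase baseline.

    Returns the first time (absolute, seconds) at which the trend exceeds
    ``mean + k * std`` of the baseline window continuously for at least
    ``min_hold_s``; None when no such excursion exists. The search starts at
    the end of the baseline window.
    """
    idx = easy_baseline.indices(trend)
    base = trend.values[idx]
    threshold = float(np.mean(base) + k * np.std(base))
    above = trend.values > threshold
    above[: idx[-1] + 1] = False
    need = max(round(min_hold_s * trend.rate), 1)
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            start = i - need + 1
            return float(trend.t0 + start / trend.rate)
    return None


def _envelope_pipeline(
    normalized: NormalizedSeries, config: PipelineConfig
) -> Tuple[EnvelopeSignal, UniformSeries]:
    """Bandpass -> square; returns the envelope and its decimated form for SSA."""
    banded = bandpass_zero_phase(
        normalized,
        low=config.bandpass_low_hz,
        high=config.bandpass_high_hz,
        order=config.bandpass_order,
    )
    envelope = square_signal(banded)
    # squaring doubles the bandwidth (up to 2 * bandpass_high); band-limit
    # again before decimating for SSA
    slow = envelope
    if config.envelope_rate_hz < envelope.rate:
        if config.envelope_lowpass_hz < envelope.rate / 2:
            slow = lowpass_zero_phase(slow, corner=config.envelope_lowpass_hz, order=8)
        factor = max(round(envelope.rate / config.envelope_rate_hz), 1)
        slow = decimate(slow, factor)
    return envelope, slow


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any failure naming the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def segment_phases(
    data,
    hold_start: float = 0.0,
    config: Optional[PipelineConfig] = None,
) -> BreathHoldPhases:
    """Segment a recording (DeviceLog or UniformSeries) into breath-hold phases.

    The easy phase runs from ``hold_start`` to the detected physiological
    breaking point; the struggle phase from there to ``conv_break_s`` (end of
    record by default). When no breaking point is detected the phases carry
    ``t_physio_break = None``.
    """
    config = config or PipelineConfig()
    config.hold_start_s = hold_start
    report = analyze_recording(data, config, want_spectrogram=False)
    return report.phases


def analyze_recording(
    data,
    config: Optional[PipelineConfig] = None,
    want_spectrogram: bool = True,
) -> AnalysisReport:
    """Run the full pipeline on a device log or raw uniform series.

    Stages, in order: conversion to a uniform series, truncation at the hold
    start, zero-phase lowpass + decimation (only when the input rate exceeds
    the 100 Hz target), easy-baseline normalization, bandpass + squaring,
    SSA trend of the decimated envelope, breaking-point detection on the
    smoothed envelope, per-phase FFT peak extraction on the normalized
    series, and a spectrogram of the envelope. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config = config or PipelineConfig()

    with _stage("to_uniform_series"):
        if isinstance(data, DeviceLog):
            series = to_uniform_series(data)
        elif isinstance(data, UniformSeries):
            series = data
        else:
            raise TypeError(f"expected DeviceLog or UniformSeries, got {type(data).__name__}")

    with _stage("truncate"):
        series = truncate_start(series, config.hold_start_s - series.t0)
    hold_start_abs = float(series.t0)

    with _stage("lowpass"):
        if series.rate > config.target_rate_hz and config.lowpass_corner_hz < series.rate / 2:
            series = lowpass_zero_phase(
                series, corner=config.lowpass_corner_hz, order=config.lowpass_order
            )
    with _stage("decimate"):
        if series.rate > config.target_rate_hz:
            factor = round(series.rate / config.target_rate_hz)
            series = decimate(series, factor)

    easy = EasyWindow(hold_start_abs, hold_start_abs + config.easy_baseline_s)
    with _stage("normalize"):
        normalized = normalize_easy(series, easy)

    with _stage("envelope"):
        envelope, slow_envelope = _envelope_pipeline(normalized, config)

    with _stage("ssa_trend"):
        window_len = min(
            round(config.ssa_window_s * slow_envelope.rate), len(slow_envelope) // 2
        )
        window_len = max(window_len, 2)
        trend = _decompose.trend_of(
            slow_envelope,
            window_len=window_len,
            trend_cutoff=config.trend_cutoff_hz,
            energy_floor=config.energy_floor,
        )

    with _stage("detect_break"):
        detection = smooth_envelope(envelope, config.detect_smooth_s)
        t_break = detect_physio_break(
            detection, easy, k=config.detect_k, min_hold_s=config.detect_min_hold_s
        )

    t_end = config.conv_break_s
    if t_end is None:
        t_end = hold_start_abs + series.duration
    phases_abs = BreathHoldPhases(
        t_hold_start=hold_start_abs, t_physio_break=t_break, t_conv_break=t_end
    )

    def _window(series_, lo, hi):
        i0 = int(np.searchsorted(series_.times, lo))
        i1 = int(np.searchsorted(series_.times, hi))
        return series_.replace(values=series_.values[i0:i1], t0=series_.times[i0] if i1 > i0 else lo)

    easy_peaks = _spectral.SpectralPeaks(peaks=())
    struggle_peaks = _spectral.SpectralPeaks(peaks=())
    easy_spec = struggle_spec = None
    with _stage("phase_fft"):
        band = (
            max(config.peak_band_hz[0], 1.5 / max(config.easy_baseline_s, 1e-9)),
            min(config.peak_band_hz[1], normalized.rate / 2),
        )
        if t_break is not None:
            easy_part = _window(normalized, hold_start_abs, t_break)
            struggle_part = _window(normalized, t_break, t_end)
        else:
            easy_part = _window(normalized, hold_start_abs, t_end)
            struggle_part = None
        if len(easy_part) >= 2:
            easy_spec = _spectral.amplitude_spectrum(easy_part)
            easy_peaks = _spectral.find_peaks(
                easy_spec, band, k=config.peak_count,
                min_prominence_fraction=config.peak_min_prominence,
            )
        if struggle_part is not None and len(struggle_part) >= 2:
            struggle_spec = _spectral.amplitude_spectrum(struggle_part)
            struggle_peaks = _spectral.find_peaks(
                struggle_spec, band, k=config.peak_count,
                min_prominence_fraction=config.peak_min_prominence,
            )

    tfmap = None
    if want_spectrogram:
        with _stage("spectrogram"):
            if config.spectrogram_window_s * envelope.rate <= len(envelope):
                tfmap = _spectral.spectrogram(
                    envelope,
                    window_s=config.spectrogram_window_s,
                    overlap_fraction=config.spectrogram_overlap,
                )

    # report times are seconds from hold start; conversion happens once, here
    def _rel(t):
        return None if t is None else t - hold_start_abs

    phases = BreathHoldPhases(
        t_hold_start=0.0,
        t_physio_break=_rel(t_break),
        t_conv_break=_rel(t_end),
    )
    trend_rel = trend.replace(t0=trend.t0 - hold_start_abs)
    normalized_rel = normalized.replace(t0=normalized.t0 - hold_start_abs)
    if tfmap is not None:
        tfmap = _spectral.TimeFreqMap(
            times=tfmap.times - hold_start_abs,
            freqs=tfmap.freqs,
            magnitude=tfmap.magnitude,
            window_s=tfmap.window_s,
            overlap_fraction=tfmap.overlap_fraction,
        )

    cfg_dict = asdict(config)
    cfg_dict["peak_band_hz"] = list(config.peak_band_hz)
    provenance = {"pipeline": cfg_dict, "hold_start_abs_s": hold_start_abs,
                  "struggle_detected": t_break is not None}
    return AnalysisReport(
        phases=phases,
        easy_peaks=easy_peaks,
        struggle_peaks=struggle_peaks,
        trend=trend_rel,
        spectrogram=tfmap,
        provenance=provenance,
        normalized=normalized_rel,
        easy_spectrum=easy_spec,
        struggle_spectrum=struggle_spec,
    )
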