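"""Model/Results interface over the breath-hold analysis pipeline.

``BreathHoldModel`` holds a recording plus pipeline configuration;
``fit()`` runs the full pipeline and returns ``BreathHoldResults`` carrying
the phase landmarks, per-phase spectral peaks, SSA trend, spectrogram and
provenance, with a plain-text ``summary()``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from . import spectral
from .logformat import DeviceLog, read_log
from .phases import AnalysisReport, PipelineConfig, analyze_recording
from .preprocess import UniformSeries


class BreathHoldModel:
    """A breath-hold recording awaiting analysis.

    Parameters
    ----------
    data : DeviceLog or UniformSeries
        The differential-acceleration recording.
    config : PipelineConfig, optional
        Pipeline parameters; defaults are the standard processing chain.
    """

    def __init__(self, data, config: Optional[PipelineConfig] = None):
        if not isinstance(data, (DeviceLog, UniformSeries)):
            raise TypeError(
                f"data must be a DeviceLog or UniformSeries, got {type(data).__name__}"
            )
        self.data = data
        self.config = config or PipelineConfig()

    @classmethod
    def from_log(cls, path: Union[str, Path], config: Optional[PipelineConfig] = None):
        """Build a model from a device CSV log on disk."""
        return cls(read_log(path), config)

    @classmethod
    def from_series(
        cls, values, rate: float, t0: float = 0.0,
        config: Optional[PipelineConfig] = None,
    ):
        """Build a model from raw samples at a uniform rate."""
        return cls(UniformSeries(values, rate, t0), config)

    def fit(self) -> "BreathHoldResults":
        """Run the analysis pipeline and return the results object."""
        report = analyze_recording(self.data, self.config)
        return BreathHoldResults(self, report)


class BreathHoldResults:
    """Fitted breath-hold analysis: landmarks, spectra, trend, provenance."""

    def __init__(self, model: BreathHoldModel, report: AnalysisReport):
        self.model = model
        self.report = report

    @property
    def phases(self):
        return self.report.phases

    @property
    def easy_peaks(self):
        return self.report.easy_peaks

    @property
    def struggle_peaks(self):
        return self.report.struggle_peaks

    @property
    def trend(self):
        return self.report.trend

    def heart_rate_bpm(self) -> Optional[int]:
        """Cardiac heart rate from the easy-phase spectral peak, in BPM."""
        if not len(self.report.easy_peaks):
            return None
        return spectral.hz_to_bpm(self.report.easy_peaks.peaks[0][0])

    def summary(self) -> str:
        """Plain-text summary table of the fitted analysis."""
        p = self.report.phases
        lines = [
            "Breath-hold analysis summary",
            "=" * 44,
            f"{'hold start (s)':<32}{p.t_hold_start:>12.2f}",
        ]
        if p.t_physio_break is not None:
            lines.append(f"{'physiological breaking point (s)':<32}{p.t_physio_break:>12.2f}")
            lines.append(f"{'easy-phase duration (s)':<32}{p.t_physio_break - p.t_hold_start:>12.2f}")
        else:
            lines.append(f"{'physiological breaking point':<32}{'not detected':>12}")
        if p.t_conv_break is not None:
            lines.append(f"{'conventional breaking point (s)':<32}{p.t_conv_break:>12.2f}")
        hr = self.heart_rate_bpm()
        if hr is not None:
            f0 = self.report.easy_peaks.peaks[0][0]
            lines.append(f"{'easy-phase cardiac peak (Hz)':<32}{f0:>12.3f}")
            lines.append(f"{'heart rate estimate (BPM)':<32}{hr:>12d}")
        if len(self.report.struggle_peaks):
            freqs = ", ".join(f"{f:.3f}" for f in self.report.struggle_peaks.freqs)
            lines.append(f"struggle-phase peaks (Hz): {freqs}")
        lines.append("=" * 44)
        return "\n".join(lines)
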