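"""Serialize analysis reports to a directory of CSV/YAML files, and render figures.

Layout: ``phases.csv``, ``peaks_easy.csv``, ``peaks_struggle.csv``,
``trend.csv``, ``spectrogram.csv`` (long format), ``provenance.yaml``, plus
``normalized.csv`` and per-phase spectra when available.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .phases import AnalysisReport, BreathHoldPhases
from .preprocess import NormalizedSeries, UniformSeries
from .spectral import SpectralPeaks, Spectrum, TimeFreqMap

REQUIRED_FILES = [
    "phases.csv",
    "peaks_easy.csv",
    "peaks_struggle.csv",
    "trend.csv",
    "spectrogram.csv",
    "provenance.yaml",
]


def _peaks_frame(peaks: SpectralPeaks) -> pd.DataFrame:
    return pd.DataFrame(
        list(peaks.peaks), columns=["freq_hz", "amplitude", "prominence"]
    )


def _series_frame(series: UniformSeries, value_col: str) -> pd.DataFrame:
    return pd.DataFrame({"time_s": series.times, value_col: series.values})


def save_report(report: AnalysisReport, out_dir) -> Path:
    """Write a report directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    p = report.phases
    pd.DataFrame(
        {
            "landmark": ["hold_start", "physio_break", "conv_break"],
            "time_s": [p.t_hold_start, p.t_physio_break, p.t_conv_break],
        }
    ).to_csv(out / "phases.csv", index=False)
    _peaks_frame(report.easy_peaks).to_csv(out / "peaks_easy.csv", index=False)
    _peaks_frame(report.struggle_peaks).to_csv(out / "peaks_struggle.csv", index=False)
    _series_frame(report.trend, "trend").to_csv(out / "trend.csv", index=False)

    if report.spectrogram is not None:
        tf = report.spectrogram
        tt, ff = np.meshgrid(tf.times, tf.freqs, indexing="ij")
        pd.DataFrame(
            {"time_s": tt.ravel(), "freq_hz": ff.ravel(), "magnitude": tf.magnitude.ravel()}
        ).to_csv(out / "spectrogram.csv", index=False)
    else:
        pd.DataFrame(columns=["time_s", "freq_hz", "magnitude"]).to_csv(
            out / "spectrogram.csv", index=False
        )

    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=True)

    if report.normalized is not None:
        _series_frame(report.normalized, "normalized").to_csv(
            out / "normalized.csv", index=False
        )
    for name, spec in (
        ("spectrum_easy.csv", report.easy_spectrum),
        ("spectrum_struggle.csv", report.struggle_spectrum),
    ):
        if spec is not None:
            pd.DataFrame({"freq_hz": spec.freqs, "amplitude": spec.amps}).to_csv(
                out / name, index=False
            )
    return out


def missing_files(report_dir) -> List[str]:
    """Names of required report files absent from a directory."""
    d = Path(report_dir)
    return [name for name in REQUIRED_FILES if not (d / name).exists()]


def load_report(report_dir) -> AnalysisReport:
    """Load a report directory written by :func:`save_report`."""
    d = Path(report_dir)
    missing = missing_files(d)
    if missing:
        raise FileNotFoundError(f"report directory {d} is missing: {', '.join(missing)}")

    phases_df = pd.read_csv(d / "phases.csv").set_index("landmark")["time_s"]

    def _opt(key):
        v = phases_df.get(key)
        return None if v is None or pd.isna(v) else float(v)

    phases = BreathHoldPhases(
        t_hold_start=float(phases_df["hold_start"]),
        t_physio_break=_opt("physio_break"),
        t_conv_break=_opt("conv_break"),
    )

    def _load_peaks(name):
        df = pd.read_csv(d / name)
        return SpectralPeaks(peaks=tuple(map(tuple, df.to_numpy())))

    trend_df = pd.read_csv(d / "trend.csv")
    t = trend_df["time_s"].to_numpy()
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    trend = UniformSeries(trend_df["trend"].to_numpy(), rate, float(t[0]) if len(t) else 0.0)

    sg_df = pd.read_csv(d / "spectrogram.csv")
    tfmap = None
    if len(sg_df):
        times = np.unique(sg_df["time_s"])
        freqs = np.unique(sg_df["freq_hz"])
        mag = sg_df["magnitude"].to_numpy().reshape(len(times), len(freqs))
        tfmap = TimeFreqMap(times=times, freqs=freqs, magnitude=mag,
                            window_s=float("nan"), overlap_fraction=float("nan"))

    with open(d / "provenance.yaml", "r", encoding="utf-8") as fh:
        provenance = yaml.safe_load(fh) or {}

    normalized = None
    if (d / "normalized.csv").exists():
        ndf = pd.read_csv(d / "normalized.csv")
        nt = ndf["time_s"].to_numpy()
        nrate = 1.0 / (nt[1] - nt[0]) if len(nt) > 1 else 1.0
        normalized = NormalizedSeries(
            ndf["normalized"].to_numpy(), nrate, float(nt[0]) if len(nt) else 0.0
        )

    def _load_spec(name):
        if not (d / name).exists():
            return None
        df = pd.read_csv(d / name)
        f = df["freq_hz"].to_numpy()
        a = df["amplitude"].to_numpy()
        n = 2 * (len(f) - 1) if len(f) > 1 else 2
        rate_ = 2 * f[-1] if len(f) > 1 else 1.0
        return Spectrum(freqs=f, amps=a, n=n, rate=float(rate_))

    return AnalysisReport(
        phases=phases,
        easy_peaks=_load_peaks("peaks_easy.csv"),
        struggle_peaks=_load_peaks("peaks_struggle.csv"),
        trend=trend,
        spectrogram=tfmap,
        provenance=provenance,
        normalized=normalized,
        easy_spectrum=_load_spec("spectrum_easy.csv"),
        struggle_spectrum=_load_spec("spectrum_struggle.csv"),
    )


def render_report(report_dir, out_dir=None) -> List[Path]:
    """Render summary figures and a text summary from a report directory.

    Produces four PNG figures (normalized trace with phase lines, per-phase
    spectra, trend, spectrogram) and ``summary.txt``; returns the written
    paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = Path(report_dir)
    out = Path(out_dir) if out_dir is not None else d
    out.mkdir(parents=True, exist_ok=True)
    report = load_report(d)
    written = []
    p = report.phases

    def _phase_lines(ax):
        for t, label in ((p.t_physio_break, "physio break"), (p.t_conv_break, "conv break")):
            if t is not None:
                ax.axvline(t, color="red", ls="--", lw=1, label=label)

    fig, ax = plt.subplots(figsize=(8, 3))
    if report.normalized is not None:
        ax.plot(report.normalized.times, report.normalized.values, lw=0.5)
        ax.set_ylabel("normalized accel")
    else:
        ax.plot(report.trend.times, report.trend.values, lw=1)
        ax.set_ylabel("trend")
    _phase_lines(ax)
    ax.set_xlabel("time from hold start (s)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    path = out / "fig_normalized.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, spec, peaks, title in (
        (axes[0], report.easy_spectrum, report.easy_peaks, "easy phase"),
        (axes[1], report.struggle_spectrum, report.struggle_peaks, "struggle phase"),
    ):
        if spec is not None:
            ax.plot(spec.freqs, spec.amps, lw=0.8)
            ax.set_xlim(0, 5)
        for f, a, _ in peaks.peaks:
            ax.plot([f], [a], "rv", ms=5)
            ax.annotate(f"{f:.3f} Hz", (f, a), fontsize=7)
        ax.set_title(title)
        ax.set_xlabel("frequency (Hz)")
    axes[0].set_ylabel("amplitude")
    fig.tight_layout()
    path = out / "fig_spectra.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(report.trend.times, report.trend.values, lw=1.2)
    _phase_lines(ax)
    ax.set_xlabel("time from hold start (s)")
    ax.set_ylabel("SSA trend (norm.²)")
    fig.tight_layout()
    path = out / "fig_trend.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(8, 3))
    if report.spectrogram is not None and report.spectrogram.magnitude.size:
        tf = report.spectrogram
        ax.pcolormesh(tf.times, tf.freqs, tf.magnitude.T, shading="auto")
        ax.set_ylim(0, 5)
    ax.set_xlabel("time from hold start (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    path = out / "fig_spectrogram.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    lines = ["breath-hold analysis summary", f"hold_start_s: {p.t_hold_start}"]
    lines.append(f"physio_break_s: {'' if p.t_physio_break is None else p.t_physio_break}")
    lines.append(f"conv_break_s: {'' if p.t_conv_break is None else p.t_conv_break}")
    if len(report.easy_peaks):
        lines.append(
            "easy_peaks_hz: " + ", ".join(f"{f:.3f}" for f in report.easy_peaks.freqs)
        )
    if len(report.struggle_peaks):
        lines.append(
            "struggle_peaks_hz: " + ", ".join(f"{f:.3f}" for f in report.struggle_peaks.freqs)
        )
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(path)
    return written
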