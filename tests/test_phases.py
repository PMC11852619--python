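"""Bandpass, envelope, breaking-point detection, and full orchestration."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ibmkit import (
    DeviceLog,
    DeviceLogRecord,
    EasyWindow,
    PipelineConfig,
    PipelineError,
    SimConfig,
    analyze_recording,
    bandpass_zero_phase,
    detect_physio_break,
    emulate_device,
    segment_phases,
    simulate_breath_hold,
    square_signal,
)
from conftest import make_series, tone


class TestBandpass:
    def test_dc_rejected(self):
        s = make_series(np.full(2000, 5.0), rate=100.0)
        out = bandpass_zero_phase(s)
        assert np.sqrt(np.mean(out.values**2)) < 1e-3 * 5.0

    def test_in_band_tone_passes_with_zero_lag(self):
        s = tone(2.0, 100.0, 60.0)
        out = bandpass_zero_phase(s, low=0.5, high=3.5, order=5)
        mid = slice(1000, -1000)
        assert np.max(np.abs(out.values[mid])) == pytest.approx(1.0, rel=0.05)
        lags = np.arange(-20, 21)
        xcorr = [np.dot(s.values[mid], np.roll(out.values, lag)[mid]) for lag in lags]
        assert lags[int(np.argmax(xcorr))] == 0

    def test_sub_band_tone_attenuated(self):
        s = tone(0.05, 100.0, 120.0)
        out = bandpass_zero_phase(s)
        mid = slice(2000, -2000)
        in_rms = np.sqrt(np.mean(s.values[mid] ** 2))
        out_rms = np.sqrt(np.mean(out.values[mid] ** 2))
        assert out_rms < 0.05 * in_rms

    def test_invalid_corners_rejected(self):
        s = make_series(np.zeros(100), rate=100.0)
        with pytest.raises(ValueError):
            bandpass_zero_phase(s, low=3.5, high=0.5)
        with pytest.raises(ValueError):
            bandpass_zero_phase(s, low=0.5, high=60.0)


class TestSquareSignal:
    def test_elementwise_square(self):
        out = square_signal(make_series([-2.0, 0.0, 3.0]))
        assert np.array_equal(out.values, [4.0, 0.0, 9.0])

    def test_non_negative_for_any_input(self):
        rng = np.random.default_rng(5)
        out = square_signal(make_series(rng.normal(size=100)))
        assert np.min(out.values) >= 0

    def test_square_is_fixed_point_under_sqrt_square(self):
        rng = np.random.default_rng(6)
        out = square_signal(make_series(rng.normal(size=50)))
        again = np.sqrt(square_signal(out).values)
        assert np.allclose(again, out.values)


class TestDetectPhysioBreak:
    def test_flat_trend_gives_absent(self):
        trend = make_series(np.ones(1000), rate=10.0)
        assert detect_physio_break(trend, EasyWindow(0.0, 10.0)) is None

    def test_step_detected_at_onset(self):
        rate = 10.0
        rng = np.random.default_rng(8)
        base = rng.normal(1.0, 0.01, 1000)
        base[500:] += 0.1 * 10  # step of 10x baseline std at t = 50 s
        trend = make_series(base, rate=rate)
        t = detect_physio_break(trend, EasyWindow(0.0, 20.0), k=3, min_hold_s=2)
        assert t == pytest.approx(50.0, abs=1 / rate)

    def test_baseline_outside_span_rejected(self):
        trend = make_series(np.ones(100), rate=10.0)
        with pytest.raises(ValueError):
            detect_physio_break(trend, EasyWindow(100.0, 110.0))

    def test_short_spike_rejected_by_dwell(self):
        rate = 10.0
        base = np.ones(1000)
        base[500:505] += 100.0  # 0.5 s spike, dwell is 2 s
        base[:200] += np.sin(np.arange(200)) * 0.01
        trend = make_series(base, rate=rate)
        assert detect_physio_break(trend, EasyWindow(0.0, 20.0), min_hold_s=2.0) is None


class TestSegmentPhases:
    def test_truth_round_trip_on_simulated_recording(self, default_log):
        config, log, truth = default_log
        phases = segment_phases(log, hold_start=truth.t_hold_start)
        assert phases.t_physio_break is not None
        detected_abs = phases.t_physio_break + truth.t_hold_start
        assert detected_abs == pytest.approx(truth.t_physio_break, abs=2.0)
        assert phases.t_hold_start == 0.0

    def test_no_struggle_means_absent_break(self):
        config = SimConfig(
            pre_hold_s=0.0, easy_s=60.0, struggle_s=0.0,
            noise_sd=0.02, artifact_events=[], seed=2,
        )
        sternum, xiphoid, _ = simulate_breath_hold(config)
        log = emulate_device(sternum, xiphoid)
        phases = segment_phases(log, hold_start=0.0)
        assert phases.t_physio_break is None


class TestAnalyzeRecording:
    def test_easy_phase_peak_at_cardiac_frequency(self, default_log):
        config, log, truth = default_log
        report = analyze_recording(log, PipelineConfig(hold_start_s=truth.t_hold_start))
        assert len(report.easy_peaks) >= 1
        bin_width = report.easy_spectrum.bin_width
        assert abs(report.easy_peaks.freqs[0] - config.cardiac_freq) <= bin_width

    def test_struggle_phase_contains_ibm_fundamental(self):
        config = SimConfig(
            ibm_f0_start=0.68, ibm_f0_end=0.68, seed=13,
        )
        sternum, xiphoid, truth = simulate_breath_hold(config)
        log = emulate_device(sternum, xiphoid)
        report = analyze_recording(log, PipelineConfig(hold_start_s=truth.t_hold_start))
        bin_width = report.struggle_spectrum.bin_width
        assert any(abs(f - 0.68) <= bin_width for f in report.struggle_peaks.freqs)

    def test_zero_signal_errors_at_normalize_stage(self):
        records = [DeviceLogRecord(tick=i * 10, diff_accel=0.0) for i in range(3000)]
        log = DeviceLog(records=records)
        with pytest.raises(PipelineError, match="normalize"):
            analyze_recording(log)

    def test_report_times_referenced_to_hold_start(self, default_log):
        config, log, truth = default_log
        report = analyze_recording(log, PipelineConfig(hold_start_s=truth.t_hold_start))
        assert report.phases.t_hold_start == 0.0
        assert report.normalized.t0 == pytest.approx(0.0)
        assert report.phases.t_conv_break == pytest.approx(
            truth.t_conv_break - truth.t_hold_start, abs=0.05
        )

    def test_pipeline_deterministic(self, default_log):
        config, log, truth = default_log
        cfg = PipelineConfig(hold_start_s=truth.t_hold_start)
        a = analyze_recording(log, cfg)
        b = analyze_recording(log, cfg)
        assert a.phases == b.phases
        assert np.array_equal(a.trend.values, b.trend.values)
        assert a.easy_peaks == b.easy_peaks

    def test_provenance_records_stage_parameters(self, default_log):
        config, log, truth = default_log
        report = analyze_recording(log, PipelineConfig(hold_start_s=truth.t_hold_start))
        assert report.provenance["pipeline"]["bandpass_low_hz"] == 0.5
        assert report.provenance["struggle_detected"] is True


class TestStrugglePhaseTrend:
    def test_trend_increases_with_growing_ibm_amplitude(self, default_log):
        """Spearman correlation between the SSA trend and time over the
        struggle window exceeds 0.8 when IBM amplitude grows."""
        config, log, truth = default_log
        report = analyze_recording(log, PipelineConfig(hold_start_s=truth.t_hold_start))
        t_break = report.phases.t_physio_break
        trend = report.trend
        mask = trend.times >= t_break
        rho, _ = spearmanr(trend.times[mask], trend.values[mask])
        assert rho > 0.8


class TestLandmarkRecovery:
    def test_breaking_point_recovered_in_most_seeded_runs(self):
        """>= 90% of 20 seeded default-condition simulations recover the
        physiological breaking point within +/-2 s."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            config = SimConfig(seed=seed)
            sternum, xiphoid, truth = simulate_breath_hold(config)
            log = emulate_device(sternum, xiphoid)
            phases = segment_phases(log, hold_start=truth.t_hold_start)
            if phases.t_physio_break is None:
                continue
            detected = phases.t_physio_break + truth.t_hold_start
            if abs(detected - truth.t_physio_break) <= 2.0:
                hits += 1
        assert hits >= 0.9 * n_runs
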