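"""Synthetic breath-hold generator and device data-path emulation."""

import numpy as np
import pytest

from ibmkit import (
    SimConfig,
    UniformSeries,
    amplitude_spectrum,
    emulate_device,
    find_peaks,
    simulate_breath_hold,
    simulate_force_plate,
)


def quiet_config(**kwargs):
    base = dict(
        pre_hold_s=5.0,
        easy_s=20.0,
        struggle_s=30.0,
        cardiac_amp=0.0,
        ibm_amp_start=0.0,
        ibm_amp_end=0.0,
        artifact_events=[],
        noise_sd=0.0,
        seed=0,
    )
    base.update(kwargs)
    return SimConfig(**base)


class TestSimulateBreathHold:
    def test_null_model_is_identically_zero(self):
        sternum, xiphoid, _ = simulate_breath_hold(quiet_config())
        assert not np.any(sternum.values)
        assert not np.any(xiphoid.values)

    def test_stream_length_matches_duration(self):
        config = quiet_config()
        sternum, _, _ = simulate_breath_hold(config)
        assert len(sternum) == round(config.total_duration * config.raw_rate)

    def test_same_seed_bit_identical(self):
        config = SimConfig(pre_hold_s=2, easy_s=5, struggle_s=5, seed=11)
        a = simulate_breath_hold(config)
        b = simulate_breath_hold(config)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_event_count_matches_rate_times_duration(self):
        config = quiet_config(
            struggle_s=60.0, ibm_f0_start=0.68, ibm_f0_end=0.68,
            ibm_amp_start=1.0, ibm_amp_end=1.0,
        )
        _, _, truth = simulate_breath_hold(config)
        assert len(truth.ibm_event_times) == pytest.approx(0.68 * 60, abs=1)

    def test_truth_landmarks_ordered_and_events_in_struggle(self):
        config = SimConfig(pre_hold_s=5, easy_s=10, struggle_s=20, seed=3)
        _, _, truth = simulate_breath_hold(config)
        assert truth.t_hold_start < truth.t_physio_break < truth.t_conv_break
        for t in truth.ibm_event_times:
            assert truth.t_physio_break <= t <= truth.t_conv_break

    def test_invalid_config_rejected_before_synthesis(self):
        with pytest.raises(ValueError):
            simulate_breath_hold(SimConfig(easy_s=-1.0))
        with pytest.raises(ValueError):
            simulate_breath_hold(SimConfig(ibm_f0_start=0.0))

    def test_ibm_bursts_scaled_by_site_gains(self):
        config = quiet_config(ibm_amp_start=2.0, ibm_amp_end=2.0,
                              xiphoid_ibm_gain=1.0, sternum_ibm_gain=0.2)
        sternum, xiphoid, _ = simulate_breath_hold(config)
        assert np.max(xiphoid.values) == pytest.approx(2.0, rel=1e-3)
        assert np.max(sternum.values) == pytest.approx(0.4, rel=1e-3)


class TestEmulateDevice:
    def test_pure_common_mode_cancels_exactly(self):
        config = quiet_config(artifact_events=[(2.0, 5.0, 1.0), (10.0, -3.0, 0.5)])
        sternum, xiphoid, _ = simulate_breath_hold(config)
        log = emulate_device(sternum, xiphoid)
        assert np.all(log.diff_accel() == 0.0)

    def test_common_mode_rejection_energy(self):
        """Artifact-only energy is rejected by far more than 120 dB."""
        config = quiet_config(artifact_events=[(3.0, 10.0, 2.0)])
        sternum, xiphoid, _ = simulate_breath_hold(config)
        log = emulate_device(sternum, xiphoid)
        in_energy = float(np.sum(sternum.values**2))
        out_energy = float(np.sum(log.diff_accel() ** 2))
        assert in_energy > 0
        assert out_energy < 1e-12 * in_energy

    def test_partial_trailing_block_dropped(self):
        s = UniformSeries(np.zeros(25), 1000.0)
        assert len(emulate_device(s, s, block=10)) == 2

    def test_block_mean(self):
        x = UniformSeries(np.arange(1.0, 11.0), 1000.0)
        z = UniformSeries(np.zeros(10), 1000.0)
        log = emulate_device(z, x, block=10)
        assert log.records[0].diff_accel == pytest.approx(5.5)

    def test_output_rate_is_raw_over_block(self):
        s = UniformSeries(np.zeros(1000), 1000.0)
        assert emulate_device(s, s, block=10).sample_rate == 100.0

    def test_mismatched_streams_rejected(self):
        a = UniformSeries(np.zeros(10), 1000.0)
        b = UniformSeries(np.zeros(11), 1000.0)
        with pytest.raises(ValueError):
            emulate_device(a, b)
        c = UniformSeries(np.zeros(10), 500.0)
        with pytest.raises(ValueError):
            emulate_device(a, c)

    def test_aux_fields_filled_at_one_hertz(self):
        s = UniformSeries(np.zeros(3000), 1000.0)
        log = emulate_device(s, s, heart_rate_bpm=120.0, spo2_pct=97.0)
        hr = [r.heart_rate for r in log.records]
        assert hr[0] == 120.0 and hr[100] == 120.0 and hr[200] == 120.0
        assert all(v is None for v in hr[1:100])


class TestForcePlate:
    def test_zero_amplitude_gives_zero_series(self):
        config = quiet_config()
        _, _, truth = simulate_breath_hold(config)
        fp = simulate_force_plate(truth, config)
        assert not np.any(fp.values)

    def test_postural_event_sign_opposite_to_differential(self):
        config = quiet_config(artifact_events=[(3.0, 5.0, 1.0)],
                              sternum_ibm_gain=0.0)
        _, xiphoid, truth = simulate_breath_hold(config)
        fp = simulate_force_plate(truth, config)
        i = np.argmax(np.abs(fp.values))
        t_ev = fp.times[i]
        j = round(t_ev * xiphoid.rate)
        assert np.sign(fp.values[i]) == -np.sign(xiphoid.values[j])

    def test_burst_argmax_at_ibm_event_times(self):
        config = quiet_config(ibm_amp_start=1.0, ibm_amp_end=3.0,
                              ibm_f0_start=0.5, ibm_f0_end=0.5)
        _, _, truth = simulate_breath_hold(config)
        fp = simulate_force_plate(truth, config)
        width = round(config.ibm_burst_width_s * fp.rate)
        for t_ev in truth.ibm_event_times:
            center = round(t_ev * fp.rate)
            lo, hi = max(center - width, 0), min(center + width, len(fp))
            local = np.argmax(fp.values[lo:hi]) + lo
            assert abs(local - center) <= 1


class TestSpectralFidelity:
    def test_struggle_differential_peak_at_configured_fundamental(self):
        """Largest sub-cardiac spectral peak within one bin of the IBM rate."""
        config = SimConfig(
            pre_hold_s=0.0, easy_s=0.0, struggle_s=60.0,
            ibm_f0_start=0.68, ibm_f0_end=0.68,
            ibm_amp_start=2.0, ibm_amp_end=2.0,
            cardiac_amp=0.5, noise_sd=0.02, artifact_events=[], seed=5,
        )
        sternum, xiphoid, truth = simulate_breath_hold(config)
        diff = UniformSeries(xiphoid.values - sternum.values, config.raw_rate)
        spec = amplitude_spectrum(diff)
        peaks = find_peaks(spec, band=(0.3, 1.0), k=1)
        assert len(peaks) == 1
        assert abs(peaks.freqs[0] - 0.68) <= spec.bin_width
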