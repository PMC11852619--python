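"""Synthetic dual-site chest-acceleration recordings of a maximal breath hold.

The recording model follows the four landmarks of a maximal static breath
hold: a pre-hold interval (postural adjustments while settling), the easy
phase (cardiac motion only), the physiological breaking point (first
involuntary breathing movement, IBM), and the struggle phase in which IBM
bursts grow in rate and amplitude until the conventional breaking point.

Two single-axis accelerometer sites are synthesized: the xiphoid process
(measurement) and the sternum (reference). Postural artifacts are
common-mode — identical on both sites — so the device's differential channel
cancels them; IBM bursts couple much more strongly into the xiphoid site.
The device data path is emulated by sample-wise differencing followed by
non-overlapping block averaging (10 raw samples per logged value by default,
1000 Hz -> 100 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .logformat import DeviceLog, DeviceLogRecord
from .preprocess import UniformSeries

# A sensor stream is one site's single-axis acceleration at a uniform rate.
SensorStream = UniformSeries


@dataclass
class SimConfig:
    """Parameters of the synthetic breath-hold recording.

    Durations are in seconds; amplitudes are in arbitrary sensor units (the
    study device logs unscaled counts). The IBM burst train repeats at a rate
    interpolating linearly from ``ibm_f0_start`` to ``ibm_f0_end`` across the
    struggle phase, with burst peak amplitudes interpolating from
    ``ibm_amp_start`` to ``ibm_amp_end``. ``artifact_events`` are common-mode
    postural disturbances: (time s, amplitude, duration s) triples applied
    identically to both sites.
    """

    pre_hold_s: float = 30.0
    easy_s: float = 100.0
    struggle_s: float = 80.0
    raw_rate: float = 1000.0
    cardiac_freq: float = 2.09
    cardiac_amp: float = 1.0
    ibm_f0_start: float = 0.6
    ibm_f0_end: float = 0.75
    ibm_amp_start: float = 2.0
    ibm_amp_end: float = 6.0
    ibm_burst_width_s: float = 0.5
    artifact_events: List[Tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 20.0, 2.0)]
    )
    noise_sd: float = 0.05
    xiphoid_ibm_gain: float = 1.0
    sternum_ibm_gain: float = 0.2
    # The xiphoid site sits closer to the heart, so the cardiac component does
    # not cancel in the differential channel.
    xiphoid_cardiac_gain: float = 1.0
    sternum_cardiac_gain: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("pre_hold_s", "easy_s", "struggle_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.raw_rate <= 2 * self.cardiac_freq:
            raise ValueError(
                f"raw_rate ({self.raw_rate} Hz) must exceed twice the cardiac "
                f"frequency ({self.cardiac_freq} Hz)"
            )
        if self.ibm_f0_start <= 0 or self.ibm_f0_end <= 0:
            raise ValueError("IBM event rates must be > 0")
        if self.ibm_burst_width_s <= 0:
            raise ValueError("ibm_burst_width_s must be > 0")
        for name in (
            "xiphoid_ibm_gain",
            "sternum_ibm_gain",
            "xiphoid_cardiac_gain",
            "sternum_cardiac_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def total_duration(self) -> float:
        return self.pre_hold_s + self.easy_s + self.struggle_s


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth annotations: the breath-hold landmarks and IBM event times."""

    t_hold_start: float
    t_physio_break: float
    t_conv_break: float
    ibm_event_times: Tuple[float, ...]
    cardiac_freq: float
    ibm_spectrum_fundamental: float

    def __post_init__(self) -> None:
        if not self.t_hold_start <= self.t_physio_break <= self.t_conv_break:
            raise ValueError("landmarks must satisfy hold_start <= physio_break <= conv_break")


def _ibm_event_times(config: SimConfig) -> List[float]:
    """Burst onset times across the struggle phase.

    The first IBM occurs at the physiological breaking point; subsequent
    events follow at the reciprocal of the instantaneous rate, which ramps
    linearly from ``ibm_f0_start`` to ``ibm_f0_end``.
    """
    t_pb = config.pre_hold_s + config.easy_s
    t_end = t_pb + config.struggle_s
    if config.struggle_s <= 0:
        return []
    events = []
    t = t_pb
    while t < t_end:
        events.append(t)
        frac = (t - t_pb) / config.struggle_s
        rate = config.ibm_f0_start + (config.ibm_f0_end - config.ibm_f0_start) * frac
        t += 1.0 / rate
    return events


def _add_bursts(
    target: np.ndarray,
    times: np.ndarray,
    events: Sequence[float],
    amps: Sequence[float],
    width_s: float,
    sign: float = 1.0,
) -> None:
    """Add raised-cosine (Hann) pulses centered at each event time, in place."""
    rate = 1.0 / (times[1] - times[0]) if times.size > 1 else 1.0
    half = width_s / 2.0
    n = target.size
    for t_ev, amp in zip(events, amps):
        i0 = max(int(math.ceil((t_ev - half) * rate)), 0)
        i1 = min(int(math.floor((t_ev + half) * rate)) + 1, n)
        if i0 >= i1:
            continue
        tt = times[i0:i1]
        target[i0:i1] += sign * amp * 0.5 * (1 + np.cos(np.pi * (tt - t_ev) / half))


def _burst_amplitudes(config: SimConfig, events: Sequence[float]) -> np.ndarray:
    t_pb = config.pre_hold_s + config.easy_s
    if config.struggle_s <= 0 or not events:
        return np.array([])
    frac = (np.asarray(events) - t_pb) / config.struggle_s
    return config.ibm_amp_start + (config.ibm_amp_end - config.ibm_amp_start) * frac


def simulate_breath_hold(
    config: SimConfig,
) -> Tuple[SensorStream, SensorStream, SimTruth]:
    """Synthesize the two sensor-site streams and the ground-truth annotations.

    Identical configurations (including ``seed``) give bit-identical output.
    """
    config.validate()
    n = round(config.total_duration * config.raw_rate)
    t = np.arange(n) / config.raw_rate

    cardiac = config.cardiac_amp * np.sin(2 * np.pi * config.cardiac_freq * t)

    common = np.zeros(n)
    for t_ev, amp, dur in config.artifact_events:
        _add_bursts(common, t, [t_ev + dur / 2.0], [amp], dur)

    events = _ibm_event_times(config)
    amps = _burst_amplitudes(config, events)
    ibm = np.zeros(n)
    _add_bursts(ibm, t, events, amps, config.ibm_burst_width_s)

    rng = np.random.default_rng(config.seed)
    noise_sternum = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
    noise_xiphoid = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0

    sternum = (
        config.sternum_cardiac_gain * cardiac
        + common
        + config.sternum_ibm_gain * ibm
        + noise_sternum
    )
    xiphoid = (
        config.xiphoid_cardiac_gain * cardiac
        + common
        + config.xiphoid_ibm_gain * ibm
        + noise_xiphoid
    )

    t_pb = config.pre_hold_s + config.easy_s
    truth = SimTruth(
        t_hold_start=config.pre_hold_s,
        t_physio_break=t_pb,
        t_conv_break=config.total_duration,
        ibm_event_times=tuple(events),
        cardiac_freq=config.cardiac_freq,
        ibm_spectrum_fundamental=config.ibm_f0_start,
    )
    return (
        SensorStream(sternum, config.raw_rate, 0.0),
        SensorStream(xiphoid, config.raw_rate, 0.0),
        truth,
    )


def emulate_device(
    sternum: SensorStream,
    xiphoid: SensorStream,
    block: int = 10,
    tick_rate: float = 1000.0,
    heart_rate_bpm: Optional[float] = None,
    spo2_pct: Optional[float] = None,
    aux_period_s: float = 1.0,
    aux_dropout: float = 0.0,
    seed: int = 0,
) -> DeviceLog:
    """Emulate the device's differential-averaging data path.

    The differential signal (xiphoid minus sternum, inward chest contraction
    positive) is averaged over consecutive non-overlapping blocks of ``block``
    raw samples and logged at ``raw_rate / block``. A trailing partial block
    is dropped. Auxiliary heart-rate / SpO2 values, when given, are filled on
    records closest to each ``aux_period_s`` boundary (the oximeter runs at
    1 Hz), optionally with random dropout; all other records leave them
    missing.
    """
    if len(sternum) != len(xiphoid):
        raise ValueError(
            f"stream lengths differ: sternum {len(sternum)}, xiphoid {len(xiphoid)}"
        )
    if sternum.rate != xiphoid.rate:
        raise ValueError(
            f"stream rates differ: sternum {sternum.rate} Hz, xiphoid {xiphoid.rate} Hz"
        )
    if block < 1 or int(block) != block:
        raise ValueError(f"block must be a positive integer, got {block}")
    block = int(block)

    diff = xiphoid.values - sternum.values
    n_blocks = len(diff) // block
    if n_blocks == 0:
        return DeviceLog(records=[], tick_rate=tick_rate, sample_rate=sternum.rate / block)
    averaged = diff[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)

    out_rate = sternum.rate / block
    ticks_per_record = tick_rate / out_rate
    rng = np.random.default_rng(seed)
    aux_every = max(round(aux_period_s * out_rate), 1)

    records = []
    for i, value in enumerate(averaged):
        hr = sp = None
        if i % aux_every == 0 and (heart_rate_bpm is not None or spo2_pct is not None):
            if aux_dropout <= 0 or rng.random() >= aux_dropout:
                hr, sp = heart_rate_bpm, spo2_pct
        records.append(
            DeviceLogRecord(tick=round(i * ticks_per_record), diff_accel=float(value),
                            heart_rate=hr, spo2=sp)
        )
    return DeviceLog(
        records=records,
        tick_rate=tick_rate,
        sample_rate=out_rate,
        source_name="emulated",
    )


def simulate_force_plate(
    truth: SimTruth, config: SimConfig, out_rate: float = 100.0
) -> UniformSeries:
    """Simulated force-plate comparison trace.

    IBM bursts appear at the same event times as on the accelerometer sites;
    large postural (common-mode) events appear with the opposite sign, since
    the plate measures the dorsal reaction while the accelerometers ride on
    the ventral chest wall.
    """
    config.validate()
    n = round(config.total_duration * out_rate)
    t = np.arange(n) / out_rate
    out = np.zeros(n)
    amps = _burst_amplitudes(config, truth.ibm_event_times)
    _add_bursts(out, t, truth.ibm_event_times, amps, config.ibm_burst_width_s)
    for t_ev, amp, dur in config.artifact_events:
        _add_bursts(out, t, [t_ev + dur / 2.0], [amp], dur, sign=-1.0)
    return UniformSeries(out, out_rate, 0.0)


def truth_to_rows(truth: SimTruth) -> List[Tuple[float, str]]:
    """Flatten annotations to (time_s, event_type) rows for the sidecar CSV."""
    rows = [
        (truth.t_hold_start, "hold_start"),
        (truth.t_physio_break, "physio_break"),
        (truth.t_conv_break, "conv_break"),
    ]
    rows.extend((t, "ibm_event") for t in truth.ibm_event_times)
    return sorted(rows)
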