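"""Device CSV log dialect: read, validate, write, and convert to uniform series.

The data logger writes one comma-separated line per averaged differential
sample, four columns: an interrupt-counter timestamp (ticks, milliseconds by
default), the averaged differential acceleration, and the auxiliary pulse
oximeter readings (heart rate in BPM, SpO2 in percent). The oximeter runs at
1 Hz and its readings are intermittent, so the auxiliary columns are usually
empty; missing means empty field, never zero.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np

from .preprocess import UniformSeries

HEADER = "tick,diff_accel,heart_rate,spo2"
_COLUMNS = HEADER.split(",")


class LogFormatError(ValueError):
    """A device log violates the CSV dialect or its invariants."""


@dataclass(frozen=True)
class DeviceLogRecord:
    """One logged sample: tick timestamp, averaged differential acceleration,
    and optional auxiliary heart rate / SpO2."""

    tick: int
    diff_accel: float
    heart_rate: Optional[float] = None
    spo2: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tick", int(self.tick))
        object.__setattr__(self, "diff_accel", float(self.diff_accel))
        if self.heart_rate is not None:
            object.__setattr__(self, "heart_rate", float(self.heart_rate))
        if self.spo2 is not None:
            object.__setattr__(self, "spo2", float(self.spo2))
        if self.heart_rate is not None and self.heart_rate <= 0:
            raise LogFormatError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise LogFormatError(f"spo2 must be in [0, 100], got {self.spo2}")


@dataclass
class DeviceLog:
    """An ordered device log plus the timing metadata needed to interpret it.

    ``tick_rate`` is the interrupt-counter frequency (ticks per second,
    default 1000: millisecond ticks); ``sample_rate`` is the nominal logging
    rate in Hz (default 100).
    """

    records: list = field(default_factory=list)
    tick_rate: float = 1000.0
    sample_rate: float = 100.0
    source_name: str = ""

    def __post_init__(self) -> None:
        ticks = [r.tick for r in self.records]
        if any(b <= a for a, b in zip(ticks, ticks[1:])):
            raise LogFormatError("ticks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def ticks(self) -> np.ndarray:
        return np.array([r.tick for r in self.records], dtype=float)

    def diff_accel(self) -> np.ndarray:
        return np.array([r.diff_accel for r in self.records], dtype=float)


def _parse_field(text: str, line_no: int, name: str, optional: bool = False):
    text = text.strip()
    if text == "":
        if optional:
            return None
        raise LogFormatError(f"line {line_no}: required field '{name}' is empty")
    try:
        return float(text)
    except ValueError:
        raise LogFormatError(
            f"line {line_no}: non-numeric value {text!r} in field '{name}'"
        ) from None


def read_log(
    source: Union[str, Path, IO[str]],
    tick_rate: float = 1000.0,
    sample_rate: float = 100.0,
) -> DeviceLog:
    """Parse a device CSV log.

    Accepts a file path or an open text stream. A leading header line is
    detected by a non-numeric first field and skipped. Raises
    :class:`LogFormatError` naming the offending line for malformed rows and
    for non-monotone timestamps.
    """
    if isinstance(source, (str, Path)):
        name = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        name = getattr(source, "name", "<stream>")
        lines = source.read().splitlines()

    records = []
    prev_tick = None
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        if line_no == 1:
            first = parts[0].strip()
            try:
                float(first)
            except ValueError:
                continue  # header line
        if len(parts) != 4:
            raise LogFormatError(
                f"line {line_no}: expected 4 comma-separated columns, got {len(parts)}"
            )
        tick_f = _parse_field(parts[0], line_no, "tick")
        if tick_f != int(tick_f):
            raise LogFormatError(f"line {line_no}: tick must be an integer, got {parts[0]!r}")
        tick = int(tick_f)
        if prev_tick is not None and tick <= prev_tick:
            raise LogFormatError(
                f"line {line_no}: tick {tick} is not greater than previous tick {prev_tick}"
            )
        prev_tick = tick
        records.append(
            DeviceLogRecord(
                tick=tick,
                diff_accel=_parse_field(parts[1], line_no, "diff_accel"),
                heart_rate=_parse_field(parts[2], line_no, "heart_rate", optional=True),
                spo2=_parse_field(parts[3], line_no, "spo2", optional=True),
            )
        )
    return DeviceLog(records=records, tick_rate=tick_rate, sample_rate=sample_rate, source_name=name)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return str(value)  # shortest round-trip repr: write -> read -> write is a fixed point


def write_log(log: DeviceLog, dest: Union[str, Path, IO[str]]) -> None:
    """Serialize a device log as 4-column CSV with a one-line header.

    Missing auxiliary values are written as empty fields. Output is parseable
    by :func:`read_log` and record-for-record equal after a round trip.
    """
    out_lines = [HEADER]
    for r in log.records:
        out_lines.append(
            f"{r.tick},{_fmt(r.diff_accel)},{_fmt(r.heart_rate)},{_fmt(r.spo2)}"
        )
    text = "\n".join(out_lines) + "\n"
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    else:
        dest.write(text)


def to_uniform_series(log: DeviceLog, gap_tolerance: float = 0.05) -> UniformSeries:
    """Convert a log to a uniformly sampled differential-acceleration series.

    The nominal inter-record interval is ``tick_rate / sample_rate`` ticks.
    Intervals within ``gap_tolerance`` (fraction of the nominal period) of one
    period are accepted; a single dropped sample (interval ~ two periods) is
    repaired by linear interpolation; anything larger or irregular is an error
    listing the gap positions.
    """
    if len(log) == 0:
        raise LogFormatError("cannot convert an empty log to a series")
    period = log.tick_rate / log.sample_rate  # ticks per sample
    ticks = log.ticks()
    values = log.diff_accel()
    out = [values[0]]
    bad_gaps = []
    for i in range(1, len(ticks)):
        delta = ticks[i] - ticks[i - 1]
        steps = round(delta / period)
        if steps < 1 or abs(delta - steps * period) > gap_tolerance * period:
            bad_gaps.append((i, delta))
        elif steps == 1:
            out.append(values[i])
        elif steps == 2:
            out.append((values[i - 1] + values[i]) / 2.0)
            out.append(values[i])
        else:
            bad_gaps.append((i, delta))
    if bad_gaps:
        desc = ", ".join(f"record {i} (gap {d:g} ticks)" for i, d in bad_gaps[:10])
        raise LogFormatError(
            f"{len(bad_gaps)} gap(s) exceed tolerance (nominal period {period:g} ticks): {desc}"
        )
    return UniformSeries(
        values=np.array(out), rate=log.sample_rate, t0=ticks[0] / log.tick_rate
    )
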