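"""Domain types and basic series manipulation shared by every pipeline stage.

The central container is :class:`MultiChannelSeries`: one ordered
``(timestamp, value)`` sequence per environmental channel, all sharing the
trace's time origin.  Timestamps are trace-relative seconds (real-valued);
no wall-clock or timezone handling anywhere.  All segment intervals are
half-open ``[start, end)`` so adjacent segments compose without
double-counting boundary samples.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

logger = logging.getLogger("adlhub")

__all__ = [
    "SensorChannel",
    "CHANNELS",
    "CHANNEL_UNITS",
    "DeviceKind",
    "EventRole",
    "Sample",
    "TriggeringEvent",
    "MultiChannelSeries",
    "SignalSegment",
    "ADLDefinition",
    "Violation",
    "slice_series",
    "validate_series",
    "concat_series",
    "AdlHubError",
    "EmptySegmentError",
    "ConfigurationError",
    "OrderingError",
    "UndefinedSlopeError",
    "InfeasibleBandError",
    "ParseError",
]


# ---------------------------------------------------------------------------
# Errors


class AdlHubError(Exception):
    """Base class for all package errors."""


class EmptySegmentError(AdlHubError):
    """A requested slice or segment contains no samples on any channel."""


class ConfigurationError(AdlHubError):
    """A configuration document is incomplete or inconsistent."""


class OrderingError(AdlHubError):
    """Samples or events arrived out of timestamp order."""


class UndefinedSlopeError(AdlHubError):
    """A regression slope was requested on degenerate data."""


class InfeasibleBandError(AdlHubError):
    """A Sakoe-Chiba band too narrow for any warping path to exist."""


class ParseError(AdlHubError):
    """A series/event/truth file failed to parse; carries a line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Enumerations


class SensorChannel(str, enum.Enum):
    """The five environmental channels sensed by the hub."""

    TEMPERATURE = "temperature"  # degrees Celsius
    HUMIDITY = "humidity"        # percent relative humidity
    ECO2 = "eco2"                # estimated CO2 equivalent, ppm
    TVOC = "tvoc"                # total volatile organic compounds, ppb
    SOUND = "sound"              # ambient sound level, uncalibrated dB

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed channel order used everywhere a deterministic order is needed.
CHANNELS: tuple[SensorChannel, ...] = tuple(SensorChannel)

CHANNEL_UNITS: dict[SensorChannel, str] = {
    SensorChannel.TEMPERATURE: "degC",
    SensorChannel.HUMIDITY: "%RH",
    SensorChannel.ECO2: "ppm",
    SensorChannel.TVOC: "ppb",
    SensorChannel.SOUND: "dB",
}


class DeviceKind(str, enum.Enum):
    """Kinds of triggering-event sources.

    ``ir_direction`` is a ceiling-mounted 2D infrared array reporting the
    direction a person moved (in/out of the unit space); ``current_tag`` and
    ``analog_tag`` report appliance usage; ``sph_emergency`` is an event a
    hub itself emits when its slope watch trips.
    """

    IR_DIRECTION = "ir_direction"
    DOOR_CONTACT = "door_contact"
    CURRENT_TAG = "current_tag"
    ANALOG_TAG = "analog_tag"
    SPH_EMERGENCY = "sph_emergency"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EventRole(str, enum.Enum):
    START = "start"
    STOP = "stop"
    POINT = "point"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class Sample:
    """One timestamped reading on one channel."""

    timestamp: float
    channel: SensorChannel
    value: float

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp {self.timestamp}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value at t={self.timestamp}")


@dataclass(frozen=True)
class TriggeringEvent:
    """Device-originated event that drives segmentation.

    ``role`` may be ``None`` on the wire; the segmenter resolves it through
    its configurable role map (which device/payload combinations open or
    close a segment is deployment configuration, not code).
    """

    timestamp: float
    device_kind: DeviceKind
    payload: Mapping[str, str] = field(default_factory=dict)
    role: Optional[EventRole] = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative event timestamp {self.timestamp}")


@dataclass(frozen=True)
class ADLDefinition:
    """One activity the hub is asked to recognise in a given unit space."""

    name: str
    space: str  # "kitchen" | "bathroom" | "other"
    expected_duration_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.expected_duration_bounds
        if not lo < hi:
            raise ValueError(
                f"ADL {self.name!r}: duration bounds must satisfy min < max, got {lo}, {hi}"
            )

    @property
    def typical_duration(self) -> float:
        lo, hi = self.expected_duration_bounds
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class Violation:
    """One broken invariant found by :func:`validate_series`."""

    channel: SensorChannel
    index: int
    rule: str
    message: str


# ---------------------------------------------------------------------------
# Series container


class MultiChannelSeries:
    """Per-channel ordered sample arrays sharing one trace time origin.

    Parameters
    ----------
    data
        Mapping from channel to ``(timestamps, values)`` array pair.
        Channels absent from the mapping are stored empty.
    sampling_interval
        Nominal spacing between consecutive samples, seconds.  Used for the
        trace span and by the simulator; irregular data is accepted.
    """

    def __init__(
        self,
        data: Mapping[SensorChannel, tuple[np.ndarray, np.ndarray]] | None = None,
        sampling_interval: float = 1.0,
    ):
        if sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        self.sampling_interval = float(sampling_interval)
        self._t: dict[SensorChannel, np.ndarray] = {}
        self._v: dict[SensorChannel, np.ndarray] = {}
        data = data or {}
        for ch in CHANNELS:
            if ch in data:
                t, v = data[ch]
                t = np.asarray(t, dtype=float)
                v = np.asarray(v, dtype=float)
                if t.shape != v.shape or t.ndim != 1:
                    raise ValueError(f"channel {ch}: timestamps/values must be 1-D and equal length")
            else:
                t = np.empty(0)
                v = np.empty(0)
            self._t[ch] = t
            self._v[ch] = v

    # -- accessors ---------------------------------------------------------

    def times(self, channel: SensorChannel) -> np.ndarray:
        return self._t[channel]

    def values(self, channel: SensorChannel) -> np.ndarray:
        return self._v[channel]

    def n_samples(self, channel: Optional[SensorChannel] = None) -> int:
        if channel is not None:
            return int(self._t[channel].size)
        return int(sum(t.size for t in self._t.values()))

    @property
    def is_empty(self) -> bool:
        return self.n_samples() == 0

    @property
    def span(self) -> float:
        """End of the trace: last timestamp plus one sampling interval.

        Defined so that ``slice_series(s, 0, s.span)`` returns every sample
        under the half-open convention.
        """
        last = [t[-1] for t in self._t.values() if t.size]
        if not last:
            return 0.0
        return float(max(last)) + self.sampling_interval

    def iter_samples(self, channel: SensorChannel) -> Iterator[Sample]:
        for t, v in zip(self._t[channel], self._v[channel]):
            yield Sample(float(t), channel, float(v))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiChannelSeries):
            return NotImplemented
        return self.sampling_interval == other.sampling_interval and all(
            np.array_equal(self._t[ch], other._t[ch])
            and np.array_equal(self._v[ch], other._v[ch])
            for ch in CHANNELS
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = {ch.value: self._t[ch].size for ch in CHANNELS}
        return f"MultiChannelSeries(n={counts}, dt={self.sampling_interval})"


class LengthMode(str, enum.Enum):
    VARIABLE = "variable"
    FIXED = "fixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SignalSegment:
    """A bounded window ``[start_t, end_t)`` of the continuous series."""

    start_t: float
    end_t: float
    series: MultiChannelSeries
    opening_event: Optional[TriggeringEvent] = None
    closing_event: Optional[TriggeringEvent] = None
    length_mode: LengthMode = LengthMode.VARIABLE

    def __post_init__(self) -> None:
        if not self.start_t < self.end_t:
            raise ValueError(f"segment bounds must satisfy start < end, got [{self.start_t}, {self.end_t})")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


__all__.append("LengthMode")


# ---------------------------------------------------------------------------
# Operations


def slice_series(
    series: MultiChannelSeries,
    start_t: float,
    end_t: float,
    *,
    opening_event: Optional[TriggeringEvent] = None,
    closing_event: Optional[TriggeringEvent] = None,
    length_mode: LengthMode = LengthMode.VARIABLE,
) -> SignalSegment:
    """Extract the half-open window ``[start_t, end_t)`` from every channel.

    Bounds outside ``[0, span]`` are clamped with a logged warning (device
    event latency can overrun trace edges).  Raises
    :class:`EmptySegmentError` if the window contains no samples on any
    channel.
    """
    if not start_t < end_t:
        raise ValueError(f"slice bounds must satisfy start < end, got [{start_t}, {end_t})")
    span = series.span
    clamped_start = min(max(start_t, 0.0), span)
    clamped_end = min(max(end_t, 0.0), span)
    if (clamped_start, clamped_end) != (start_t, end_t):
        logger.warning(
            "slice [%s, %s) clamped to [%s, %s) (trace span %s)",
            start_t, end_t, clamped_start, clamped_end, span,
        )
        start_t, end_t = clamped_start, clamped_end
        if not start_t < end_t:
            raise EmptySegmentError(f"slice clamped to an empty interval at trace edge (span {span})")

    data = {}
    total = 0
    for ch in CHANNELS:
        t = series.times(ch)
        lo = int(np.searchsorted(t, start_t, side="left"))
        hi = int(np.searchsorted(t, end_t, side="left"))
        data[ch] = (t[lo:hi], series.values(ch)[lo:hi])
        total += hi - lo
    if total == 0:
        raise EmptySegmentError(f"no samples in [{start_t}, {end_t}) on any channel")
    sub = MultiChannelSeries(data, sampling_interval=series.sampling_interval)
    return SignalSegment(
        start_t=start_t,
        end_t=end_t,
        series=sub,
        opening_event=opening_event,
        closing_event=closing_event,
        length_mode=length_mode,
    )


def validate_series(series: MultiChannelSeries) -> list[Violation]:
    """Report every broken invariant; never raises.

    Checks, per channel: timestamps non-negative, strictly increasing, and
    all values finite.  Each violation names the channel, the sample index
    and the rule broken.
    """
    violations: list[Violation] = []
    for ch in CHANNELS:
        t = series.times(ch)
        v = series.values(ch)
        if t.size and t[0] < 0:
            violations.append(Violation(ch, 0, "non_negative_timestamp",
                                        f"{ch.value}[0]: timestamp {t[0]} < 0"))
        bad = np.nonzero(np.diff(t) <= 0)[0]
        for i in bad:
            violations.append(Violation(ch, int(i) + 1, "strictly_increasing_timestamps",
                                        f"{ch.value}[{i + 1}]: timestamp {t[i + 1]} <= previous {t[i]}"))
        nonfinite = np.nonzero(~np.isfinite(v))[0]
        for i in nonfinite:
            violations.append(Violation(ch, int(i), "finite_value",
                                        f"{ch.value}[{i}]: non-finite value"))
    return violations


def concat_series(parts: Iterable[MultiChannelSeries]) -> MultiChannelSeries:
    """Concatenate consecutive disjoint series (e.g. adjacent slices)."""
    parts = list(parts)
    if not parts:
        return MultiChannelSeries()
    data = {
        ch: (
            np.concatenate([p.times(ch) for p in parts]),
            np.concatenate([p.values(ch) for p in parts]),
        )
        for ch in CHANNELS
    }
    return MultiChannelSeries(data, sampling_interval=parts[0].sampling_interval)
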