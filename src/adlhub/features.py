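"""Constant-memory, single-pass feature extraction.

A :class:`RunningStats` accumulates, per channel, everything the scoring
stage and the emergency watch need -- duration, mean, high/low peak, and
the four sums an ordinary-least-squares slope requires -- without ever
storing the segment's samples.  The mean uses the incremental (Welford
style) update; the slope accumulators re-base timestamps to the window's
first sample so ``sum(t^2)`` stays well-conditioned on long traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import (
    CHANNELS,
    EmptySegmentError,
    OrderingError,
    Sample,
    SensorChannel,
    SignalSegment,
    UndefinedSlopeError,
)

__all__ = [
    "ChannelStats",
    "RunningStats",
    "ChannelFeatures",
    "FeatureVector",
    "update",
    "finalize",
    "window_slope",
    "merge",
    "segment_stats",
    "FEATURE_NAMES",
]

#: The four scalar features extracted per channel, in canonical order.
FEATURE_NAMES: tuple[str, ...] = ("duration", "mean", "peak_high", "peak_low")


@dataclass
class ChannelStats:
    """Streaming accumulators for one channel.

    ``st/sv/stv/stt`` are the OLS sums over re-based time ``t' = t - first_t``.
    ``t_at_max`` tracks when the running maximum was last raised, which the
    emergency pre-check uses as the rise-to-peak duration.
    """

    count: int = 0
    first_t: float = 0.0
    last_t: float = 0.0
    mean: float = 0.0
    vmax: float = -math.inf
    vmin: float = math.inf
    t_at_max: float = 0.0
    st: float = 0.0
    sv: float = 0.0
    stv: float = 0.0
    stt: float = 0.0

    def push(self, t: float, v: float, channel: SensorChannel) -> None:
        if self.count and t < self.last_t:
            raise OrderingError(
                f"channel {channel.value}: sample at t={t} after t={self.last_t}"
            )
        if self.count == 0:
            self.first_t = t
        self.count += 1
        self.last_t = t
        self.mean += (v - self.mean) / self.count
        if v > self.vmax:
            self.vmax = v
            self.t_at_max = t
        if v < self.vmin:
            self.vmin = v
        tr = t - self.first_t
        self.st += tr
        self.sv += v
        self.stv += tr * v
        self.stt += tr * tr


class RunningStats:
    """Per-channel streaming summary of an (implicit) segment."""

    def __init__(self) -> None:
        self.channels: dict[SensorChannel, ChannelStats] = {ch: ChannelStats() for ch in CHANNELS}

    def update(self, sample: Sample) -> "RunningStats":
        self.channels[sample.channel].push(sample.timestamp, sample.value, sample.channel)
        return self

    def update_many(self, channel: SensorChannel, times: np.ndarray, values: np.ndarray) -> "RunningStats":
        """Feed an ordered block of samples for one channel.

        Same arithmetic as sample-at-a-time :meth:`update`; exists so the
        pipeline does not build a Sample object per reading.
        """
        cs = self.channels[channel]
        for t, v in zip(times, values):
            cs.push(float(t), float(v), channel)
        return self


@dataclass(frozen=True)
class ChannelFeatures:
    duration: float
    mean: float
    peak_high: float
    peak_low: float
    #: seconds from the window's first sample to the sample at which the
    #: high peak was (last) attained; consumed by the emergency pre-check.
    rise_to_peak: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not self.peak_low <= self.mean <= self.peak_high:
            raise ValueError("features must satisfy peak_low <= mean <= peak_high")

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class FeatureVector:
    """Finalized per-channel duration/mean/peak summary of one segment."""

    channels: Mapping[SensorChannel, ChannelFeatures]

    def __getitem__(self, channel: SensorChannel) -> ChannelFeatures:
        return self.channels[channel]

    def to_row(self) -> dict[str, float]:
        """Flatten to a CSV-ready row, columns named ``<channel>.<feature>``."""
        row: dict[str, float] = {}
        for ch in CHANNELS:
            cf = self.channels[ch]
            for name in FEATURE_NAMES:
                row[f"{ch.value}.{name}"] = cf[name]
        return row


def update(stats: RunningStats, sample: Sample) -> RunningStats:
    """Fold one sample into the running summary (constant time and memory)."""
    return stats.update(sample)


def finalize(stats: RunningStats, *, require_all_channels: bool = True) -> FeatureVector:
    """Freeze the accumulators into a :class:`FeatureVector`.

    Idempotent: finalizing twice returns identical values.  Raises
    :class:`EmptySegmentError` if a required channel received no samples.
    """
    out: dict[SensorChannel, ChannelFeatures] = {}
    for ch in CHANNELS:
        cs = stats.channels[ch]
        if cs.count == 0:
            if require_all_channels:
                raise EmptySegmentError(f"channel {ch.value}: no samples to finalize")
            continue
        out[ch] = ChannelFeatures(
            duration=cs.last_t - cs.first_t,
            mean=cs.mean,
            peak_high=cs.vmax,
            peak_low=cs.vmin,
            rise_to_peak=cs.t_at_max - cs.first_t,
        )
    if not out:
        raise EmptySegmentError("no channel has any samples")
    return FeatureVector(channels=out)


def window_slope(stats: RunningStats, channel: SensorChannel) -> float:
    """OLS slope of value against time for one channel, units per second.

    ``slope = (n*Stv - St*Sv) / (n*Stt - St^2)`` over re-based timestamps.
    Raises :class:`UndefinedSlopeError` with fewer than two distinct
    timestamps.
    """
    cs = stats.channels[channel]
    if cs.count < 2:
        raise UndefinedSlopeError(f"channel {channel.value}: need >= 2 samples, have {cs.count}")
    denom = cs.count * cs.stt - cs.st * cs.st
    if denom <= 0:
        raise UndefinedSlopeError(f"channel {channel.value}: all timestamps equal")
    return (cs.count * cs.stv - cs.st * cs.sv) / denom


def merge(a: RunningStats, b: RunningStats) -> RunningStats:
    """Combine two summaries of consecutive disjoint windows.

    Requires every non-empty channel of ``b`` to start no earlier than the
    corresponding channel of ``a`` ends.
    """
    out = RunningStats()
    for ch in CHANNELS:
        ca, cb = a.channels[ch], b.channels[ch]
        if ca.count and cb.count and cb.first_t < ca.last_t:
            raise OrderingError(f"channel {ch.value}: windows overlap or are out of order")
        first, second = (ca, cb) if ca.count else (cb, ca)
        co = out.channels[ch]
        if not first.count:
            continue
        n1, n2 = first.count, second.count
        co.count = n1 + n2
        co.first_t = first.first_t
        co.last_t = second.last_t if n2 else first.last_t
        co.mean = (n1 * first.mean + n2 * second.mean) / (n1 + n2)
        if second.count and second.vmax > first.vmax:
            co.vmax, co.t_at_max = second.vmax, second.t_at_max
        else:
            co.vmax, co.t_at_max = first.vmax, first.t_at_max
        co.vmin = min(first.vmin, second.vmin if n2 else math.inf)
        # re-base second window's time sums onto first.first_t:
        # t' = (t - b.first_t) + d  with  d = b.first_t - a.first_t
        co.sv = first.sv + second.sv
        if n2:
            d = second.first_t - first.first_t
            co.st = first.st + second.st + n2 * d
            co.stv = first.stv + second.stv + d * second.sv
            co.stt = first.stt + second.stt + 2 * d * second.st + n2 * d * d
        else:
            co.st, co.stv, co.stt = first.st, first.stv, first.stt
    return out


def segment_stats(segment: SignalSegment) -> RunningStats:
    """Stream every channel of a segment through a fresh RunningStats."""
    stats = RunningStats()
    for ch in CHANNELS:
        stats.update_many(ch, segment.series.times(ch), segment.series.values(ch))
    return stats
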