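"""Two-layer emergency screening.

Layer 1 (*watch*): a continuous linear-regression slope check over the
most recent short window of each channel; a situation is normal while the
absolute regression slope stays small, an emergency once it grows too
large on any channel.

Layer 2 (*pre-check*): before a segment's features reach the scoring
stage, excessively steep-and-abnormal profiles are intercepted -- a high
peak reached too quickly.  This is what separates a fire (large, fast
temperature excursion) from cooking (a gradual, moderate one): both raise
the temperature, but with very different magnitude and rise duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import (
    CHANNELS,
    DeviceKind,
    EventRole,
    MultiChannelSeries,
    SensorChannel,
    TriggeringEvent,
    UndefinedSlopeError,
    logger,
)
from .features import FeatureVector, RunningStats, window_slope

__all__ = [
    "EmergencyThresholds",
    "Verdict",
    "watch",
    "precheck",
    "watch_trace",
    "default_thresholds",
]


@dataclass(frozen=True)
class EmergencyThresholds:
    """Per-channel screening bounds (all strictly positive).

    max_abs_slope: watch trips when |slope| exceeds this, units/s.
    peak_bound: pre-check absolute level a peak must exceed, channel units.
    max_rise_duration: pre-check window within which that peak must have
    been reached, seconds.  A channel absent from a mapping is not screened.
    """

    max_abs_slope: Mapping[SensorChannel, float] = field(default_factory=dict)
    peak_bound: Mapping[SensorChannel, float] = field(default_factory=dict)
    max_rise_duration: Mapping[SensorChannel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.max_abs_slope, self.peak_bound, self.max_rise_duration):
            for ch, v in m.items():
                if v <= 0:
                    raise ValueError(f"threshold for {ch.value} must be > 0, got {v}")


@dataclass(frozen=True)
class Verdict:
    """Outcome of a screening layer: normal/pass, or emergency(channel)."""

    emergency: bool
    channel: Optional[SensorChannel] = None

    def __bool__(self) -> bool:
        return self.emergency


def default_thresholds() -> EmergencyThresholds:
    """Screening bounds calibrated on the simulator's default signatures.

    Temperature dominates: a fire climbs >0.1 degC/s initially and tops
    30 degC within minutes, while the hottest cooking profile climbs about
    0.01 degC/s and peaks near 26 degC.  TVOC/eCO2 bounds catch smoulder
    profiles; humidity and sound are not screened.
    """
    T, C, V = SensorChannel.TEMPERATURE, SensorChannel.ECO2, SensorChannel.TVOC
    return EmergencyThresholds(
        max_abs_slope={T: 0.05, C: 30.0, V: 40.0},
        peak_bound={T: 30.0, C: 1200.0, V: 1400.0},
        max_rise_duration={T: 600.0, C: 600.0, V: 600.0},
    )


def watch(stats: RunningStats, thresholds: EmergencyThresholds) -> Verdict:
    """Slope watch over one short window.

    Emergency iff ``|slope| > max_abs_slope`` (strict) on any monitored
    channel; the first offending channel in the fixed channel order is
    reported.  An undefined slope is treated as normal and logged.
    """
    for ch in CHANNELS:
        bound = thresholds.max_abs_slope.get(ch)
        if bound is None:
            continue
        try:
            slope = window_slope(stats, ch)
        except UndefinedSlopeError:
            logger.info("watch: slope undefined on %s; treated as normal", ch.value)
            continue
        if abs(slope) > bound:
            return Verdict(True, ch)
    return Verdict(False)


def precheck(fv: FeatureVector, thresholds: EmergencyThresholds) -> Verdict:
    """Feature-level screen applied before scoring.

    Emergency iff, on some monitored channel, ``peak_high`` strictly
    exceeds the peak bound AND the rise to that peak completed strictly
    within the rise-duration bound.  Everything else passes through to the
    scoring stage.
    """
    for ch in CHANNELS:
        peak_bound = thresholds.peak_bound.get(ch)
        rise_bound = thresholds.max_rise_duration.get(ch)
        if peak_bound is None or rise_bound is None:
            continue
        if ch not in fv.channels:
            continue
        cf = fv[ch]
        if cf.peak_high > peak_bound and cf.rise_to_peak < rise_bound:
            return Verdict(True, ch)
    return Verdict(False)


def watch_trace(
    series: MultiChannelSeries,
    thresholds: EmergencyThresholds,
    window: float = 60.0,
) -> list[TriggeringEvent]:
    """Run the slope watch over a whole trace in tumbling windows.

    Single pass, constant memory per window.  Each window that trips emits
    one hub-emergency notification event stamped at the window end --
    mirroring a hub notifying its peers -- which downstream stages record
    as a point event.  The 60 s default window is the length of the "recent
    history" queue the watch observes; a declared design choice.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    events: list[TriggeringEvent] = []
    span = series.span
    n_windows = int(np.ceil(span / window))
    for k in range(n_windows):
        lo, hi = k * window, min((k + 1) * window, span)
        stats = RunningStats()
        any_samples = False
        for ch in CHANNELS:
            t = series.times(ch)
            i0 = int(np.searchsorted(t, lo, side="left"))
            i1 = int(np.searchsorted(t, hi, side="left"))
            if i1 > i0:
                any_samples = True
                stats.update_many(ch, t[i0:i1], series.values(ch)[i0:i1])
        if not any_samples:
            continue
        verdict = watch(stats, thresholds)
        if verdict:
            events.append(
                TriggeringEvent(
                    timestamp=hi,
                    device_kind=DeviceKind.SPH_EMERGENCY,
                    payload={"channel": verdict.channel.value},
                    role=EventRole.POINT,
                )
            )
    return events
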