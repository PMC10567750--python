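"""Event-driven segmentation of the continuous series.

A small state machine: a start-role event opens a segment, a stop-role
event closes it, a superseding start closes the current segment and
immediately reopens (back-to-back behaviours -- segments never nest), and
an open segment that outlives ``max_segment_len`` is closed as a
fixed-length segment by the clock tick.  Which device/payload combinations
count as start vs stop is configuration (the role map), not code, because
the devices present differ per room.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .core import (
    DeviceKind,
    EmptySegmentError,
    EventRole,
    LengthMode,
    MultiChannelSeries,
    SignalSegment,
    TriggeringEvent,
    logger,
    slice_series,
)

__all__ = ["EventRoleMap", "default_role_map", "Segmenter", "segment_stream"]


@dataclass(frozen=True)
class EventRoleMap:
    """Resolves an event to its segmentation role.

    ``rules`` maps ``(device_kind, payload_key, payload_value)`` to a role;
    ``kind_defaults`` maps a bare device kind.  Events matching nothing
    fall back to the role carried on the event itself, else ``point``.
    """

    rules: dict[tuple[DeviceKind, str, str], EventRole] = field(default_factory=dict)
    kind_defaults: dict[DeviceKind, EventRole] = field(default_factory=dict)

    def resolve(self, event: TriggeringEvent) -> EventRole:
        for key, value in event.payload.items():
            role = self.rules.get((event.device_kind, key, str(value)))
            if role is not None:
                return role
        role = self.kind_defaults.get(event.device_kind)
        if role is not None:
            return role
        return event.role if event.role is not None else EventRole.POINT


def default_role_map() -> EventRoleMap:
    """Direction in/out and appliance on/off open/close; hub emergency
    notifications are recorded as point events.  An infrared "out" closes
    any open segment regardless of what opened it."""
    K = DeviceKind
    return EventRoleMap(
        rules={
            (K.IR_DIRECTION, "direction", "in"): EventRole.START,
            (K.IR_DIRECTION, "direction", "out"): EventRole.STOP,
            (K.DOOR_CONTACT, "state", "open"): EventRole.START,
            (K.DOOR_CONTACT, "state", "closed"): EventRole.STOP,
            (K.CURRENT_TAG, "state", "on"): EventRole.START,
            (K.CURRENT_TAG, "state", "off"): EventRole.STOP,
            (K.ANALOG_TAG, "state", "on"): EventRole.START,
            (K.ANALOG_TAG, "state", "off"): EventRole.STOP,
        },
        kind_defaults={K.SPH_EMERGENCY: EventRole.POINT},
    )


class Segmenter:
    """Two-state (idle/open) segmenter over a timestamp-ordered event stream."""

    def __init__(
        self,
        role_map: Optional[EventRoleMap] = None,
        max_segment_len: float = 1800.0,
    ):
        if max_segment_len <= 0:
            raise ValueError("max_segment_len must be positive")
        self.role_map = role_map or default_role_map()
        self.max_segment_len = float(max_segment_len)
        self.mode: str = "idle"
        self.opening_event: Optional[TriggeringEvent] = None
        self.opened_at: Optional[float] = None
        self.point_events: list[TriggeringEvent] = []
        self._last_seen: float = 0.0

    # -- internals ---------------------------------------------------------

    def _emit(
        self,
        series: MultiChannelSeries,
        end_t: float,
        closing_event: Optional[TriggeringEvent],
        length_mode: LengthMode,
    ) -> Optional[SignalSegment]:
        assert self.opened_at is not None
        start_t, opening = self.opened_at, self.opening_event
        self.mode, self.opened_at, self.opening_event = "idle", None, None
        self.point_events = []
        if not start_t < end_t:
            logger.warning("segment at t=%s closed with no extent; dropped", start_t)
            return None
        try:
            return slice_series(
                series, start_t, end_t,
                opening_event=opening, closing_event=closing_event,
                length_mode=length_mode,
            )
        except EmptySegmentError:
            logger.warning("segment [%s, %s) contains no samples; dropped", start_t, end_t)
            return None

    # -- public API --------------------------------------------------------

    def on_event(
        self, event: TriggeringEvent, series: MultiChannelSeries
    ) -> Optional[SignalSegment]:
        """Advance the state machine by one event; maybe emit a segment."""
        if event.timestamp < self._last_seen:
            logger.warning("event at t=%s out of order (last t=%s)", event.timestamp, self._last_seen)
        self._last_seen = max(self._last_seen, event.timestamp)
        role = self.role_map.resolve(event)
        emitted: Optional[SignalSegment] = None
        if role is EventRole.START:
            if self.mode == "open":
                # superseding start: close at the new event, reopen at once
                emitted = self._emit(series, event.timestamp, event, LengthMode.VARIABLE)
            self.mode = "open"
            self.opening_event = event
            self.opened_at = event.timestamp
        elif role is EventRole.STOP:
            if self.mode == "open":
                emitted = self._emit(series, event.timestamp, event, LengthMode.VARIABLE)
            else:
                logger.warning("stop event at t=%s while idle; ignored", event.timestamp)
        else:  # point
            if self.mode == "open":
                self.point_events.append(event)
        return emitted

    def on_tick(self, now: float, series: MultiChannelSeries) -> Optional[SignalSegment]:
        """Clock tick: time out an over-long open segment (boundary inclusive)."""
        self._last_seen = max(self._last_seen, now)
        if self.mode == "open" and self.opened_at is not None:
            if now - self.opened_at >= self.max_segment_len:
                return self._emit(
                    series, self.opened_at + self.max_segment_len, None, LengthMode.FIXED
                )
        return None


def segment_stream(
    series: MultiChannelSeries,
    events: Sequence[TriggeringEvent],
    role_map: Optional[EventRoleMap] = None,
    max_segment_len: float = 1800.0,
) -> list[SignalSegment]:
    """Replay an ordered event stream against a recorded series.

    Equivalent to delivering each event through :meth:`Segmenter.on_event`
    with a clock tick at every sampling instant: between events the only
    tick that can matter is the timeout instant, so it is delivered
    directly.  A segment still open at the end of the trace is timed out if
    over-long, otherwise discarded with a warning.
    """
    seg = Segmenter(role_map=role_map, max_segment_len=max_segment_len)
    out: list[SignalSegment] = []
    for ev in sorted(events, key=lambda e: e.timestamp):
        if seg.mode == "open" and seg.opened_at is not None:
            timeout_at = seg.opened_at + seg.max_segment_len
            if ev.timestamp >= timeout_at:
                s = seg.on_tick(timeout_at, series)
                if s is not None:
                    out.append(s)
        s = seg.on_event(ev, series)
        if s is not None:
            out.append(s)
    if seg.mode == "open" and seg.opened_at is not None:
        end = series.span
        if end - seg.opened_at >= seg.max_segment_len:
            s = seg.on_tick(seg.opened_at + seg.max_segment_len, series)
            if s is not None:
                out.append(s)
        else:
            logger.warning("segment opened at t=%s never closed before trace end; dropped", seg.opened_at)
    return out
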