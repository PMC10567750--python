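"""Predefined weight-factor mapping: the scoring classifier.

Each segment's per-channel duration/mean/peak features are min-max
normalized against configured reference ranges, multiplied by a per-ADL,
per-channel, per-feature weight table, and summed; the raw score is then
adjusted by a device base weight factor keyed on the event class that
opened the segment (different devices -- water usage, microwave usage,
door traffic -- carry different evidence about the activity).  The ADL
with the highest final score wins.

The reference deployment's weights were determined empirically and never
published; the default table here is produced the same way, by
:func:`calibrate_weight_table`: simulate one noise-free prototype episode
per ADL, extract and normalize its features, and use the L2-normalized
feature vector as that ADL's weight row.  With unit-norm rows the final
score is proportional to the cosine similarity between a segment and each
ADL's prototype, so each prototype is its own argmax -- a transparent,
deterministic calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    ADLDefinition,
    CHANNELS,
    ConfigurationError,
    SensorChannel,
    TriggeringEvent,
)
from .features import FEATURE_NAMES, FeatureVector, finalize, segment_stats

__all__ = [
    "NormalizationRanges",
    "WeightTable",
    "ADLScorecard",
    "normalize",
    "score",
    "estimate",
    "event_class",
    "default_ranges",
    "calibrate_weight_table",
    "default_weight_table",
]


@dataclass(frozen=True)
class NormalizationRanges:
    """Reference [lo, hi) ranges per (channel, feature), natural units."""

    ranges: Mapping[tuple[SensorChannel, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for (ch, feat), (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {ch.value}.{feat}: lo must be < hi, got {lo}, {hi}")

    def get(self, channel: SensorChannel, feature: str) -> tuple[float, float]:
        try:
            return self.ranges[(channel, feature)]
        except KeyError:
            raise ConfigurationError(
                f"no normalization range configured for {channel.value}.{feature}"
            ) from None


@dataclass(frozen=True)
class WeightTable:
    """Sensor weights w[adl][channel][feature] plus device base weights.

    Device weights are keyed by event class (see :func:`event_class`);
    unknown classes fall back to ``default_device_weight``.
    """

    sensor: Mapping[str, Mapping[SensorChannel, Mapping[str, float]]]
    device: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    default_device_weight: float = 1.0
    #: "multiplicative": final = raw * d; "additive": final = raw + (d - 1).
    device_mode: str = "multiplicative"
    #: optional reject floor: a winner whose final score falls below this is
    #: reported as "unknown" (off by default).
    score_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.device_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown device_mode {self.device_mode!r}")
        for adl, per_ch in self.sensor.items():
            for ch in CHANNELS:
                if ch not in per_ch:
                    raise ConfigurationError(f"weight table: ADL {adl!r} missing channel {ch.value}")
                for feat in FEATURE_NAMES:
                    w = per_ch[ch].get(feat)
                    if w is None:
                        raise ConfigurationError(
                            f"weight table: ADL {adl!r} missing {ch.value}.{feat}"
                        )
                    if w < 0:
                        raise ConfigurationError(
                            f"weight table: ADL {adl!r} {ch.value}.{feat} is negative"
                        )

    def device_weight(self, adl: str, cls: Optional[str]) -> float:
        per_adl = self.device.get(adl, {})
        if cls is None:
            return self.default_device_weight
        return float(per_adl.get(cls, self.default_device_weight))


@dataclass(frozen=True)
class ADLScorecard:
    """Raw and device-adjusted scores for every candidate ADL."""

    raw: Mapping[str, float]
    final: Mapping[str, float]
    winner: str
    margin: float
    tie: bool = False

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def event_class(event: Optional[TriggeringEvent]) -> Optional[str]:
    """Canonical device-class string of an event, for device-weight lookup.

    ``current_tag`` events carrying an appliance identifier refine to
    ``current_tag:<appliance>``; everything else is the bare device kind.
    """
    if event is None:
        return None
    appliance = event.payload.get("appliance")
    if appliance:
        return f"{event.device_kind.value}:{appliance}"
    return event.device_kind.value


def normalize(fv: FeatureVector, ranges: NormalizationRanges) -> dict[SensorChannel, dict[str, float]]:
    """Min-max map each feature to [0, 1]: ``(x - lo) / (hi - lo)``, clamped."""
    out: dict[SensorChannel, dict[str, float]] = {}
    for ch in CHANNELS:
        cf = fv[ch]
        out[ch] = {}
        for feat in FEATURE_NAMES:
            lo, hi = ranges.get(ch, feat)
            x = (cf[feat] - lo) / (hi - lo)
            out[ch][feat] = min(1.0, max(0.0, x))
    return out


def score(
    nfv: Mapping[SensorChannel, Mapping[str, float]],
    table: WeightTable,
    adl: str,
) -> float:
    """Raw score: sum over channels and features of weight times feature."""
    if adl not in table.sensor:
        raise ConfigurationError(f"ADL {adl!r} not present in weight table")
    per_ch = table.sensor[adl]
    total = 0.0
    for ch in CHANNELS:
        for feat in FEATURE_NAMES:
            total += per_ch[ch][feat] * nfv[ch][feat]
    return total


def estimate(
    fv: FeatureVector,
    opening_event: Optional[TriggeringEvent],
    table: WeightTable,
    ranges: NormalizationRanges,
    catalog: Sequence[ADLDefinition],
) -> ADLScorecard:
    """Score every catalogued ADL and pick the highest final score.

    The catalog should already be restricted to the segment's unit space.
    Ties are broken by lexicographic ADL name with the tie flag set.
    """
    if not catalog:
        raise ConfigurationError("estimate: empty ADL catalog")
    nfv = normalize(fv, ranges)
    cls = event_class(opening_event)
    raw: dict[str, float] = {}
    final: dict[str, float] = {}
    for adl in sorted(d.name for d in catalog):
        r = score(nfv, table, adl)
        d = table.device_weight(adl, cls)
        raw[adl] = r
        final[adl] = r * d if table.device_mode == "multiplicative" else r + (d - 1.0)
    ordered = sorted(final.items(), key=lambda kv: (-kv[1], kv[0]))
    winner, best = ordered[0]
    runner_up = ordered[1][1] if len(ordered) > 1 else 0.0
    margin = best - runner_up if len(ordered) > 1 else best
    tie = len(ordered) > 1 and best == runner_up
    if table.score_floor is not None and best < table.score_floor:
        winner = "unknown"
    return ADLScorecard(raw=raw, final=final, winner=winner, margin=max(margin, 0.0), tie=tie)


# ---------------------------------------------------------------------------
# Default configuration


def default_ranges() -> NormalizationRanges:
    """Reference feature ranges spanning the simulator's operating envelope."""
    T, H, C, V, S = CHANNELS
    r: dict[tuple[SensorChannel, str], tuple[float, float]] = {}
    for ch in CHANNELS:
        r[(ch, "duration")] = (0.0, 1800.0)
    r[(T, "mean")] = (18.0, 30.0)
    r[(T, "peak_high")] = (18.0, 36.0)
    r[(T, "peak_low")] = (16.0, 30.0)
    r[(H, "mean")] = (30.0, 70.0)
    r[(H, "peak_high")] = (30.0, 80.0)
    r[(H, "peak_low")] = (25.0, 60.0)
    r[(C, "mean")] = (300.0, 1200.0)
    r[(C, "peak_high")] = (300.0, 1500.0)
    r[(C, "peak_low")] = (250.0, 900.0)
    r[(V, "mean")] = (0.0, 800.0)
    r[(V, "peak_high")] = (0.0, 1800.0)
    r[(V, "peak_low")] = (0.0, 400.0)
    r[(S, "mean")] = (30.0, 55.0)
    r[(S, "peak_high")] = (30.0, 60.0)
    r[(S, "peak_low")] = (25.0, 45.0)
    return NormalizationRanges(r)


def calibrate_weight_table(
    signatures: Mapping[str, "ADLSignature"],  # noqa: F821 - forward ref, see simulate
    catalog: Mapping[str, ADLDefinition],
    ranges: Optional[NormalizationRanges] = None,
    *,
    lead_in: float = 600.0,
) -> WeightTable:
    """Derive sensor weights empirically from noise-free prototype episodes.

    For each catalogued ADL, simulate a single noise-free episode of its
    typical duration, stream it through the feature extractor, min-max
    normalize, and L2-normalize the resulting 20-vector into the ADL's
    weight row.  Device weights default to the neutral 1.0.
    """
    from .segmentation import segment_stream  # local import avoids a cycle
    from .simulate import Episode, LatencyModel, ScenarioScript, simulate

    ranges = ranges or default_ranges()
    sensor: dict[str, dict[SensorChannel, dict[str, float]]] = {}
    zero_latency = LatencyModel(0.0, 0.0, 0.0, 0.0)
    for name, definition in sorted(catalog.items()):
        dur = definition.typical_duration
        script = ScenarioScript(
            episodes=[Episode(name, lead_in, dur)],
            trace_span=lead_in + dur + lead_in,
            space=definition.space,
            seed=0,
        )
        series, events, _ = simulate(script, signatures, zero_latency)
        segments = segment_stream(series, events)
        if len(segments) != 1:  # pragma: no cover - calibration sanity
            raise ConfigurationError(f"calibration for {name!r} produced {len(segments)} segments")
        fv = finalize(segment_stats(segments[0]))
        nfv = normalize(fv, ranges)
        flat = np.array([nfv[ch][feat] for ch in CHANNELS for feat in FEATURE_NAMES])
        norm = float(np.linalg.norm(flat))
        if norm == 0:
            raise ConfigurationError(f"calibration for {name!r} produced an all-zero feature vector")
        flat /= norm
        row: dict[SensorChannel, dict[str, float]] = {}
        k = 0
        for ch in CHANNELS:
            row[ch] = {}
            for feat in FEATURE_NAMES:
                row[ch][feat] = float(flat[k])
                k += 1
        sensor[name] = row
    return WeightTable(sensor=sensor)


def default_weight_table() -> WeightTable:
    """Calibrated weights for the default signatures and catalog."""
    from .simulate import default_catalog, default_signatures

    return calibrate_weight_table(default_signatures(), default_catalog())
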