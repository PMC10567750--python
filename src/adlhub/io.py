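"""File formats: series CSV, event NDJSON, truth CSV, YAML configuration.

Series files are plain CSV ``timestamp,channel,value`` with one sample per
row, '.' decimal separator, values written with full ``repr`` precision so
a write-then-read round trip is exact.  Events are NDJSON, one record per
line.  All configuration (signatures, weight tables, normalization ranges,
thresholds, scenario scripts) lives in YAML documents.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNELS,
    DeviceKind,
    EventRole,
    MultiChannelSeries,
    ParseError,
    SensorChannel,
    TriggeringEvent,
)
from .emergency import EmergencyThresholds
from .evaluation import PredictedEvent
from .features import FEATURE_NAMES
from .pwfma import NormalizationRanges, WeightTable
from .simulate import ADLSignature, ChannelResponse

__all__ = [
    "read_series", "write_series",
    "read_events", "write_events",
    "read_truth", "write_truth",
    "write_references", "read_references",
    "load_config", "dump_config",
    "signatures_to_obj", "signatures_from_obj",
    "weight_table_to_obj", "weight_table_from_obj",
    "ranges_to_obj", "ranges_from_obj",
    "thresholds_to_obj", "thresholds_from_obj",
]

PathLike = Union[str, Path]
_CHANNEL_NAMES = {ch.value for ch in SensorChannel}


# ---------------------------------------------------------------------------
# Series CSV


def write_series(series: MultiChannelSeries, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp,channel,value\n")
        for ch in CHANNELS:
            for t, v in zip(series.times(ch), series.values(ch)):
                fh.write(f"{float(t)!r},{ch.value},{float(v)!r}\n")


def read_series(path: PathLike, sampling_interval: float = 1.0) -> MultiChannelSeries:
    """Parse a series CSV; errors carry 1-based file line numbers."""
    try:
        df = pd.read_csv(path, dtype={"timestamp": str, "channel": str, "value": str})
    except Exception as exc:  # pragma: no cover - malformed beyond repair
        raise ParseError(f"cannot read series CSV {path}: {exc}") from exc
    expected = ["timestamp", "channel", "value"]
    if list(df.columns) != expected:
        raise ParseError(f"series CSV must have header {','.join(expected)}", line=1)
    data: dict[SensorChannel, tuple[list[float], list[float]]] = {ch: ([], []) for ch in CHANNELS}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        name = row.channel
        if name not in _CHANNEL_NAMES:
            raise ParseError(f"unknown channel {name!r}", line=idx)
        try:
            t = float(row.timestamp)
            v = float(row.value)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric timestamp/value {row.timestamp!r},{row.value!r}", line=idx) from None
        ch = SensorChannel(name)
        ts, vs = data[ch]
        if ts and t <= ts[-1]:
            raise ParseError(f"non-monotone timestamp {t} on channel {name}", line=idx)
        ts.append(t)
        vs.append(v)
    arrays = {ch: (np.array(ts), np.array(vs)) for ch, (ts, vs) in data.items()}
    return MultiChannelSeries(arrays, sampling_interval=sampling_interval)


# ---------------------------------------------------------------------------
# Events NDJSON


def write_events(events: Sequence[TriggeringEvent], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ev in events:
            rec = {
                "timestamp": ev.timestamp,
                "device_kind": ev.device_kind.value,
                "payload": dict(ev.payload),
                "role": ev.role.value if ev.role is not None else None,
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_events(path: PathLike) -> list[TriggeringEvent]:
    events: list[TriggeringEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for idx, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc.msg}", line=idx) from exc
            try:
                events.append(
                    TriggeringEvent(
                        timestamp=float(rec["timestamp"]),
                        device_kind=DeviceKind(rec["device_kind"]),
                        payload=rec.get("payload") or {},
                        role=EventRole(rec["role"]) if rec.get("role") else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"invalid event record: {exc}", line=idx) from exc
    return events


# ---------------------------------------------------------------------------
# Truth / predictions CSV  (`adl,start,end`)


def write_truth(entries: Sequence, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("adl,start,end\n")
        for e in entries:
            start = float(getattr(e, "start"))
            end = float(getattr(e, "end"))
            fh.write(f"{e.adl},{start!r},{end!r}\n")


def read_truth(path: PathLike) -> list[PredictedEvent]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read truth CSV {path}: {exc}") from exc
    if list(df.columns) != ["adl", "start", "end"]:
        raise ParseError("truth CSV must have header adl,start,end", line=1)
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(PredictedEvent(str(row.adl), float(row.start), float(row.end)))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"invalid truth row: {exc}", line=idx) from None
    return out


# ---------------------------------------------------------------------------
# Reference signals: CSV matrix + JSON sidecar


def write_references(references: Sequence, directory: PathLike) -> None:
    from .dtw import ReferenceSignal  # noqa: F401 - typing only

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ref in references:
        frame = pd.DataFrame({ch.value: ref.channels[ch] for ch in CHANNELS if ch in ref.channels})
        frame.insert(0, "grid_index", np.arange(ref.grid_len))
        frame.to_csv(directory / f"{ref.adl}.csv", index=False)
        meta = {"adl": ref.adl, "source_count": ref.source_count, "grid_len": ref.grid_len}
        (directory / f"{ref.adl}.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_references(directory: PathLike) -> list:
    from .dtw import ReferenceSignal

    directory = Path(directory)
    refs = []
    for meta_path in sorted(directory.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        frame = pd.read_csv(directory / f"{meta['adl']}.csv")
        channels = {
            SensorChannel(col): frame[col].to_numpy(dtype=float)
            for col in frame.columns
            if col in _CHANNEL_NAMES
        }
        refs.append(ReferenceSignal(adl=meta["adl"], channels=channels,
                                    source_count=int(meta["source_count"])))
    return refs


# ---------------------------------------------------------------------------
# YAML (de)serialization of configuration objects


def signatures_to_obj(signatures: Mapping[str, ADLSignature]) -> dict:
    obj = {}
    for name, sig in sorted(signatures.items()):
        obj[name] = {
            "space": sig.space,
            "responses": {
                ch.value: {
                    "amplitude": r.amplitude,
                    "rise_tau": r.rise_tau,
                    "decay_tau": r.decay_tau,
                }
                for ch, r in sorted(sig.responses.items(), key=lambda kv: kv[0].value)
            },
            "noise_sd": {ch.value: sd for ch, sd in sorted(sig.noise_sd.items(), key=lambda kv: kv[0].value)},
        }
    return obj


def signatures_from_obj(obj: Mapping) -> dict[str, ADLSignature]:
    out = {}
    for name, spec in obj.items():
        responses = {
            SensorChannel(ch): ChannelResponse(
                float(r["amplitude"]), float(r["rise_tau"]), float(r["decay_tau"])
            )
            for ch, r in spec.get("responses", {}).items()
        }
        noise = {SensorChannel(ch): float(sd) for ch, sd in spec.get("noise_sd", {}).items()}
        out[name] = ADLSignature(name=name, space=spec["space"], responses=responses, noise_sd=noise)
    return out


def weight_table_to_obj(table: WeightTable) -> dict:
    return {
        "sensor": {
            adl: {ch.value: dict(feats) for ch, feats in per_ch.items()}
            for adl, per_ch in sorted(table.sensor.items())
        },
        "device": {adl: dict(m) for adl, m in sorted(table.device.items())},
        "default_device_weight": table.default_device_weight,
        "device_mode": table.device_mode,
        "score_floor": table.score_floor,
    }


def weight_table_from_obj(obj: Mapping) -> WeightTable:
    sensor = {
        adl: {SensorChannel(ch): {f: float(w) for f, w in feats.items()} for ch, feats in per_ch.items()}
        for adl, per_ch in obj["sensor"].items()
    }
    return WeightTable(
        sensor=sensor,
        device=obj.get("device", {}),
        default_device_weight=float(obj.get("default_device_weight", 1.0)),
        device_mode=obj.get("device_mode", "multiplicative"),
        score_floor=obj.get("score_floor"),
    )


def ranges_to_obj(ranges: NormalizationRanges) -> dict:
    obj: dict = {}
    for (ch, feat), (lo, hi) in sorted(ranges.ranges.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        obj.setdefault(ch.value, {})[feat] = [lo, hi]
    return obj


def ranges_from_obj(obj: Mapping) -> NormalizationRanges:
    ranges = {
        (SensorChannel(ch), feat): (float(pair[0]), float(pair[1]))
        for ch, feats in obj.items()
        for feat, pair in feats.items()
    }
    return NormalizationRanges(ranges)


def thresholds_to_obj(thresholds: EmergencyThresholds) -> dict:
    return {
        "max_abs_slope": {ch.value: v for ch, v in sorted(thresholds.max_abs_slope.items(), key=lambda kv: kv[0].value)},
        "peak_bound": {ch.value: v for ch, v in sorted(thresholds.peak_bound.items(), key=lambda kv: kv[0].value)},
        "max_rise_duration": {ch.value: v for ch, v in sorted(thresholds.max_rise_duration.items(), key=lambda kv: kv[0].value)},
    }


def thresholds_from_obj(obj: Mapping) -> EmergencyThresholds:
    def conv(m: Mapping) -> dict[SensorChannel, float]:
        return {SensorChannel(ch): float(v) for ch, v in m.items()}

    return EmergencyThresholds(
        max_abs_slope=conv(obj.get("max_abs_slope", {})),
        peak_bound=conv(obj.get("peak_bound", {})),
        max_rise_duration=conv(obj.get("max_rise_duration", {})),
    )


def load_config(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ParseError(f"config {path} must be a YAML mapping")
    return obj


def dump_config(obj: Mapping, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True, default_flow_style=False)
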