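"""Correct / false / miss evaluation of predicted activity events.

Predictions are matched one-to-one against a caregiver-style ground-truth
log (non-overlapping labelled intervals).  A prediction matches a truth
entry when their temporal overlap covers at least ``overlap_frac`` of the
truth entry's duration.  A matched prediction with the same label is a
*correct* detection; matched with a different label, a *false* detection
charged to the truth entry's activity ("detected, but detected
differently"); an unmatched truth entry is a *miss* ("happened, but not
detected").  Detections whose label is outside the targeted activity set
land in an extra *activity* tally.  Per activity,

    accuracy = 100 * correct / (correct + false + miss)

which is the only formula consistent with the reference deployment's
printed evaluation tables.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PredictedEvent",
    "GroundTruthLog",
    "Counts",
    "DetectionReport",
    "match_events",
    "accuracy",
    "report_tables",
]


@dataclass(frozen=True)
class PredictedEvent:
    adl: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"prediction {self.adl}: start must be < end")


@dataclass(frozen=True)
class GroundTruthLog:
    """Labelled truth intervals for one unit space; must be non-overlapping."""

    entries: Sequence[PredictedEvent]
    space: str = ""

    def __post_init__(self) -> None:
        ordered = sorted(self.entries, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"ground truth overlaps: {a.adl} [{a.start},{a.end}) and {b.adl} [{b.start},{b.end})"
                )


@dataclass
class Counts:
    correct: int = 0
    false: int = 0
    miss: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.false + self.miss


@dataclass
class DetectionReport:
    """Per-activity correct/false/miss counts plus the untargeted tally."""

    per_adl: dict[str, Counts] = field(default_factory=dict)
    activity: int = 0
    space: str = ""

    def counts(self, adl: str) -> Counts:
        return self.per_adl.setdefault(adl, Counts())

    def accuracy(self, adl: str) -> Optional[float]:
        c = self.per_adl.get(adl, Counts())
        return accuracy(c.correct, c.false, c.miss)

    def overall_accuracy(self) -> Optional[float]:
        correct = sum(c.correct for c in self.per_adl.values())
        false = sum(c.false for c in self.per_adl.values())
        miss = sum(c.miss for c in self.per_adl.values())
        return accuracy(correct, false, miss)


def _overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def match_events(
    predictions: Sequence[PredictedEvent],
    truth: GroundTruthLog,
    targeted: Iterable[str],
    overlap_frac: float = 0.5,
) -> DetectionReport:
    """Greedy one-to-one matching of predictions to truth entries.

    Truth entries are processed in start-time order; each takes the
    still-unmatched prediction with the largest overlap among those
    covering at least ``overlap_frac`` of the truth duration (ties by
    earliest prediction start, making the result independent of input
    order).  Every truth entry becomes exactly one of correct, false or
    miss; unmatched predictions with untargeted labels are tallied as
    generic activity.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    targeted = set(targeted)
    report = DetectionReport(space=truth.space)
    for name in sorted(targeted):
        report.counts(name)
    preds = sorted(predictions, key=lambda p: (p.start, p.end, p.adl))
    matched = [False] * len(preds)
    for entry in sorted(truth.entries, key=lambda e: e.start):
        need = overlap_frac * (entry.end - entry.start)
        best_i, best_ov = None, -1.0
        for i, p in enumerate(preds):
            if matched[i]:
                continue
            ov = _overlap(p.start, p.end, entry.start, entry.end)
            if ov >= need and ov > best_ov:
                best_i, best_ov = i, ov
        c = report.counts(entry.adl)
        if best_i is None:
            c.miss += 1
        else:
            matched[best_i] = True
            if preds[best_i].adl == entry.adl:
                c.correct += 1
            else:
                c.false += 1
    for i, p in enumerate(preds):
        if not matched[i] and p.adl not in targeted:
            report.activity += 1
    return report


def accuracy(correct: int, false: int, miss: int) -> Optional[float]:
    """Percent of truth events detected correctly, one-decimal rounding.

    ``100 * correct / (correct + false + miss)``; a zero denominator is
    undefined and reported as ``None``, never as 0.
    """
    denom = correct + false + miss
    if denom <= 0:
        return None
    return round(100.0 * correct / denom, 1)


def report_tables(reports: Mapping[str, DetectionReport],
                  adl_order: Optional[Mapping[str, Sequence[str]]] = None) -> dict[str, str]:
    """Render one evaluation table per unit space.

    Returns ``{space: {"csv": ..., "text": ...}}`` flattened as
    ``{f"{space}.csv": ..., f"{space}.text": ...}``; rows are
    Correct/False/Miss/Accuracy, one column per targeted activity plus the
    generic Activity tally.
    """
    out: dict[str, str] = {}
    for space, report in sorted(reports.items()):
        if adl_order and space in adl_order:
            names = list(adl_order[space])
        else:
            names = sorted(report.per_adl)
        header = ["metric", *names, "activity"]
        rows: list[list[str]] = []
        for metric in ("correct", "false", "miss"):
            row = [metric.capitalize()]
            for n in names:
                row.append(str(getattr(report.counts(n), metric)))
            row.append(str(report.activity) if metric == "correct" else "*")
            rows.append(row)
        acc_row = ["Accuracy"]
        for n in names:
            a = report.accuracy(n)
            acc_row.append("undefined" if a is None else f"{a:.1f}%")
        acc_row.append("*")
        rows.append(acc_row)

        buf = io.StringIO()
        buf.write(",".join(header) + "\n")
        for row in rows:
            buf.write(",".join(row) + "\n")
        out[f"{space}.csv"] = buf.getvalue()

        widths = [max(len(str(x)) for x in col) for col in zip(header, *rows)]
        lines = ["  ".join(str(x).ljust(w) for x, w in zip(header, widths)).rstrip()]
        for row in rows:
            lines.append("  ".join(str(x).ljust(w) for x, w in zip(row, widths)).rstrip())
        out[f"{space}.text"] = "\n".join(lines) + "\n"
    return out
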