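"""Reference-signal construction and DTW nearest-reference classification.

For each activity, labelled instances are linearly resampled onto a fixed
grid over their own time support and averaged pointwise into a single
"answer" signal.  A new segment is classified by summing, over channels,
the dynamic-time-warping distance between the segment and each reference,
and picking the closest.

The DTW recurrence is the classic one -- local cost ``|a_i - b_j|``, steps
(i-1,j), (i,j-1), (i-1,j-1) -- with an optional Sakoe-Chiba band.  Each DP
row is computed vectorised: with ``m_j = min(prev_j, prev_{j-1})`` the
in-row recurrence ``D_j = c_j + min(m_j, D_{j-1})`` telescopes to a running
minimum over prefix sums of the local costs, so no Python-level inner loop
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    CHANNELS,
    EmptySegmentError,
    InfeasibleBandError,
    SensorChannel,
    SignalSegment,
    logger,
)

__all__ = [
    "ReferenceSignal",
    "build_reference",
    "dtw_distance",
    "classify",
    "resample_segment",
    "znorm",
]


@dataclass(frozen=True)
class ReferenceSignal:
    """Average "answer" signal for one activity on a common grid."""

    adl: str
    channels: Mapping[SensorChannel, np.ndarray]
    source_count: int

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1 or min(lengths) < 2:
            raise ValueError("reference channels must share one length >= 2")
        if self.source_count < 1:
            raise ValueError("source_count must be >= 1")

    @property
    def grid_len(self) -> int:
        return len(next(iter(self.channels.values())))


def _resample_channel(t: np.ndarray, v: np.ndarray, grid_len: int) -> np.ndarray:
    """Linear interpolation of one channel onto ``grid_len`` evenly spaced
    points spanning its own sample support."""
    grid = np.linspace(t[0], t[-1], grid_len)
    return np.interp(grid, t, v)


def resample_segment(segment: SignalSegment, grid_len: int) -> dict[SensorChannel, np.ndarray]:
    """Resample every non-empty channel of a segment to the common grid."""
    if grid_len < 2:
        raise ValueError("grid_len must be >= 2")
    out: dict[SensorChannel, np.ndarray] = {}
    for ch in CHANNELS:
        t = segment.series.times(ch)
        if t.size == 0:
            continue
        if t.size == 1:
            out[ch] = np.full(grid_len, float(segment.series.values(ch)[0]))
        else:
            out[ch] = _resample_channel(t, segment.series.values(ch), grid_len)
    if not out:
        raise EmptySegmentError("segment has no samples on any channel")
    return out


def build_reference(
    instances: Sequence[SignalSegment], grid_len: int, *, adl: str = ""
) -> ReferenceSignal:
    """Pointwise mean of resampled labelled instances.

    Instances with an empty channel are skipped for that channel with a
    warning; an empty instance list is an error.
    """
    if not instances:
        raise ValueError("build_reference: need at least one instance")
    if grid_len < 2:
        raise ValueError("grid_len must be >= 2")
    channels: dict[SensorChannel, np.ndarray] = {}
    for ch in CHANNELS:
        rows = []
        for k, seg in enumerate(instances):
            t = seg.series.times(ch)
            if t.size < 1:
                logger.warning("build_reference(%s): instance %d empty on %s; skipped",
                               adl, k, ch.value)
                continue
            if t.size == 1:
                rows.append(np.full(grid_len, float(seg.series.values(ch)[0])))
            else:
                rows.append(_resample_channel(t, seg.series.values(ch), grid_len))
        if rows:
            channels[ch] = np.mean(rows, axis=0)
    if not channels:
        raise ValueError("build_reference: every instance empty on every channel")
    return ReferenceSignal(adl=adl, channels=channels, source_count=len(instances))


def dtw_distance(a: np.ndarray, b: np.ndarray, band: Optional[int] = None) -> float:
    """Dynamic-time-warping cost between two 1-D sequences.

    Local cost ``|a_i - b_j|``; symmetric step pattern; boundary at (1,1);
    returns D(n, m).  ``band`` restricts the warping path to
    ``|i - j| <= band`` (Sakoe-Chiba); a band that admits no path raises
    :class:`InfeasibleBandError`.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("dtw_distance: sequences must be non-empty")
    if band is not None:
        if band < 0:
            raise InfeasibleBandError("band must be >= 0")
        if abs(n - m) > band:
            raise InfeasibleBandError(
                f"band {band} smaller than length difference |{n} - {m}|"
            )

    inf = np.inf
    prev = np.full(m, inf)
    for i in range(n):
        jlo = 0 if band is None else max(0, i - band)
        jhi = m - 1 if band is None else min(m - 1, i + band)
        c = np.abs(a[i] - b[jlo:jhi + 1])
        cur = np.full(m, inf)
        if i == 0:
            # first row: D[0, j] = sum(c[0..j]) (only rightward moves)
            cur[jlo:jhi + 1] = np.cumsum(c)
        else:
            up = prev[jlo:jhi + 1]                       # (i-1, j)
            diag = np.empty(jhi + 1 - jlo)               # (i-1, j-1)
            diag[0] = inf if jlo == 0 else prev[jlo - 1]
            diag[1:] = prev[jlo:jhi]
            mcol = np.minimum(up, diag)
            # D[i,j] = c[j] + min(mcol[j], D[i,j-1])  ==  telescoped scan:
            s = np.cumsum(c)
            e = np.minimum.accumulate(mcol - (s - c))
            cur[jlo:jhi + 1] = e + s
        prev = cur
    d = float(prev[-1])
    if not np.isfinite(d):  # pragma: no cover - unreachable with diagonal steps
        raise InfeasibleBandError("no warping path satisfies the band constraint")
    return d


def znorm(x: np.ndarray) -> np.ndarray:
    """Z-normalize to mean 0, sd 1; a constant sequence maps to all zeros."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        return np.zeros_like(x)
    return (x - float(np.mean(x))) / sd


def classify(
    segment: SignalSegment,
    references: Sequence[ReferenceSignal],
    grid_len: int = 100,
    *,
    normalized: bool = True,
    band: Optional[int] = None,
) -> tuple[str, dict[str, float]]:
    """Nearest-reference label for a segment.

    The segment is resampled to the common grid; with ``normalized`` (the
    default) every channel of both segment and reference is z-normalized
    first so channels with large natural units do not dominate the
    multichannel sum.  Total distance is the sum of per-channel DTW costs
    over the channels present in both; the reference with the minimal total
    wins (lexicographic tie-break).
    """
    if not references:
        raise ValueError("classify: no references")
    seg_channels = resample_segment(segment, grid_len)
    if normalized:
        seg_channels = {ch: znorm(v) for ch, v in seg_channels.items()}
    totals: dict[str, float] = {}
    for ref in references:
        total = 0.0
        for ch in CHANNELS:
            if ch not in seg_channels or ch not in ref.channels:
                continue
            rv = ref.channels[ch]
            if normalized:
                rv = znorm(rv)
            total += dtw_distance(seg_channels[ch], rv, band=band)
        totals[ref.adl] = total
    winner = min(sorted(totals), key=lambda k: totals[k])
    return winner, totals
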