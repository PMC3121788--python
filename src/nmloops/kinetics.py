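"""Digestion time-course analysis.

A limited-DNase-I digestion of a nucleoid sample is summarized as the
percentage of DNA still attached to the nuclear matrix (NM) at each
sampled time.  The analysis here is deliberately model-free: local
finite-difference slopes between consecutive time points, the terminal
plateau, and the mapping of the non-zero time points onto ordered
topological zones (D = distal, P = proximal, VC = very close,
E = embedded, from outermost to innermost relative to the NM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "TimePoint",
    "DigestionTimeCourse",
    "SlopeInterval",
    "SlopeTable",
    "ZoneBin",
    "ZoneScheme",
    "ComparisonReport",
    "local_slopes",
    "plateau_fraction",
    "zone_scheme_from_timepoints",
    "compare_timecourses",
    "round_half_away",
    "DEFAULT_ZONE_LABELS",
]

DEFAULT_ZONE_LABELS = ("D", "P", "VC", "E")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round to `decimals` with ties going away from zero (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TimePoint:
    time_min: float
    pct_attached: float
    sd: float = math.nan
    n: int = 1


@dataclass(frozen=True)
class DigestionTimeCourse:
    """% NM-attached DNA versus digestion time for one sample/age group."""

    label: str
    points: tuple

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if not pts:
            raise InvalidParameterError("time course needs at least one point")
        times = [p.time_min for p in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError(f"{self.label}: times must be strictly increasing")
        if times[0] != 0.0:
            raise InvalidParameterError(f"{self.label}: first time point must be 0")
        if pts[0].pct_attached != 100.0:
            raise InvalidParameterError(f"{self.label}: attached DNA at t=0 must be 100.0%")
        for p in pts:
            if not (0.0 <= p.pct_attached <= 100.0):
                raise InvalidParameterError(
                    f"{self.label}: pct_attached {p.pct_attached} at t={p.time_min} "
                    "outside [0, 100]"
                )

    @property
    def times(self) -> tuple:
        return tuple(p.time_min for p in self.points)

    @property
    def values(self) -> tuple:
        return tuple(p.pct_attached for p in self.points)

    @classmethod
    def from_arrays(cls, label, times, pcts, sds=None, ns=None) -> "DigestionTimeCourse":
        k = len(times)
        sds = [math.nan] * k if sds is None else list(sds)
        ns = [1] * k if ns is None else list(ns)
        pts = tuple(
            TimePoint(float(t), float(v), float(s), int(n))
            for t, v, s, n in zip(times, pcts, sds, ns)
        )
        return cls(label=label, points=pts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "time_min": list(self.times),
                "pct_attached": list(self.values),
                "sd": [p.sd for p in self.points],
                "n": [p.n for p in self.points],
            }
        )


@dataclass(frozen=True)
class SlopeInterval:
    t_start: float
    t_end: float
    raw_slope: float
    rounded_slope: float


@dataclass(frozen=True)
class SlopeTable:
    """Local slopes S (percentage points per minute) between consecutive time points."""

    label: str
    intervals: tuple

    @property
    def raw(self) -> tuple:
        return tuple(iv.raw_slope for iv in self.intervals)

    @property
    def rounded(self) -> tuple:
        return tuple(iv.rounded_slope for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "t_start": [iv.t_start for iv in self.intervals],
                "t_end": [iv.t_end for iv in self.intervals],
                "raw_slope": [iv.raw_slope for iv in self.intervals],
                "rounded_slope": [iv.rounded_slope for iv in self.intervals],
            }
        )


def local_slopes(tc: DigestionTimeCourse, decimals: int = 1) -> SlopeTable:
    """Finite-difference slope over each consecutive time-point pair.

    Raw slope is (pct(t_{i+1}) - pct(t_i)) / (t_{i+1} - t_i); the rounded
    value uses round-half-away-from-zero, which is how bench reports
    conventionally round.  A positive raw slope (attached DNA increasing
    in time) is physically impossible under digestion and is surfaced as
    a warning attribute on the table rather than an error.
    """
    if len(tc.points) < 2:
        raise InvalidParameterError("local_slopes needs at least 2 time points")
    intervals = []
    for a, b in zip(tc.points, tc.points[1:]):
        dt = b.time_min - a.time_min
        if dt <= 0:
            raise InvalidParameterError(f"{tc.label}: duplicate/non-increasing times")
        raw = (b.pct_attached - a.pct_attached) / dt
        intervals.append(SlopeInterval(a.time_min, b.time_min, raw, round_half_away(raw, decimals)))
    table = SlopeTable(label=tc.label, intervals=tuple(intervals))
    object.__setattr__(table, "qc_positive_slopes", tuple(iv for iv in intervals if iv.raw_slope > 0))
    return table


def plateau_fraction(tc: DigestionTimeCourse) -> float:
    """% attached at the final sampled time (the non-digestible plateau)."""
    return tc.points[-1].pct_attached


@dataclass(frozen=True)
class ZoneBin:
    label: str
    timepoint_min: float
    slope: float = math.nan  # slope magnitude of the interval ending at this time
    sd: float = math.nan  # SD of the time-course value at this time (reporting only)


@dataclass(frozen=True)
class ZoneScheme:
    """Ordered topological zones bound to digestion time points.

    Outermost zone first (shortest digestion that clears it), innermost
    (embedded) last.  Distance ranks count outward from the NM: the
    innermost zone has rank 1.
    """

    zones: tuple

    def __post_init__(self) -> None:
        zs = tuple(self.zones)
        object.__setattr__(self, "zones", zs)
        labels = [z.label for z in zs]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("zone labels must be unique")
        times = [z.timepoint_min for z in zs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("zone time points must be strictly increasing")

    @property
    def labels(self) -> tuple:
        return tuple(z.label for z in self.zones)

    @property
    def timepoints(self) -> tuple:
        return tuple(z.timepoint_min for z in self.zones)

    def timepoint_for(self, label: str) -> float:
        for z in self.zones:
            if z.label == label:
                return z.timepoint_min
        raise KeyError(f"no zone labelled {label!r}")

    def rank(self, label: str) -> int:
        """Distance rank: innermost zone = 1, increasing outward."""
        labels = self.labels
        if label not in labels:
            raise KeyError(f"no zone labelled {label!r}")
        return len(labels) - labels.index(label)


def zone_scheme_from_timepoints(tc: DigestionTimeCourse, labels=DEFAULT_ZONE_LABELS) -> ZoneScheme:
    """Bind ordered zone labels to the non-zero digestion time points.

    Zone i gets the i-th non-zero time point; each zone also carries the
    magnitude of the local slope over the interval that ends at its time
    point plus the reported SD there, for reporting.
    """
    nonzero = [p for p in tc.points if p.time_min > 0]
    if len(nonzero) != len(labels):
        raise InvalidParameterError(
            f"{tc.label}: {len(labels)} zone labels for {len(nonzero)} non-zero time points"
        )
    slopes = local_slopes(tc) if len(tc.points) >= 2 else None
    zones = []
    for i, (lab, p) in enumerate(zip(labels, nonzero)):
        slope = abs(slopes.intervals[i].raw_slope) if slopes else math.nan
        zones.append(ZoneBin(label=lab, timepoint_min=p.time_min, slope=slope, sd=p.sd))
    return ZoneScheme(zones=tuple(zones))


@dataclass(frozen=True)
class ComparisonReport:
    label_a: str
    label_b: str
    times: tuple
    differences: tuple  # pct_a - pct_b at shared non-zero times
    slower_label: str | None
    crossing: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "difference_pct": self.differences})


def compare_timecourses(tc_a: DigestionTimeCourse, tc_b: DigestionTimeCourse) -> ComparisonReport:
    """Which sample digests more slowly (retains more NM-attached DNA)?

    The slower course must dominate at every shared non-zero time point;
    crossing curves yield no winner and set the crossing flag.
    """
    if tc_a.times != tc_b.times:
        raise InvalidParameterError(
            f"time grids differ: {tc_a.label} {tc_a.times} vs {tc_b.label} {tc_b.times}"
        )
    times, da, db = [], [], []
    for pa, pb in zip(tc_a.points, tc_b.points):
        if pa.time_min == 0:
            continue
        times.append(pa.time_min)
        da.append(pa.pct_attached)
        db.append(pb.pct_attached)
    diffs = tuple(np.subtract(da, db))
    a_dom = all(x >= y for x, y in zip(da, db))
    b_dom = all(y >= x for x, y in zip(da, db))
    if a_dom and b_dom:  # identical
        slower, crossing = None, False
    elif a_dom:
        slower, crossing = tc_a.label, False
    elif b_dom:
        slower, crossing = tc_b.label, False
    else:
        slower, crossing = None, True
    return ComparisonReport(
        label_a=tc_a.label,
        label_b=tc_b.label,
        times=tuple(times),
        differences=diffs,
        slower_label=slower,
        crossing=crossing,
    )


def compare_with_published(
    table: SlopeTable, published: tuple, decimals: int = 1
) -> pd.DataFrame:
    """Discrepancy report between recomputed and published local slopes.

    One row per interval with the recomputed raw and rounded slope, the
    published value, and whether they agree at the printed precision.
    Published tables occasionally carry entries that are not the
    finite-difference of their own percentages; such entries come out
    flagged (matches == False) rather than special-cased.
    """
    if len(published) != len(table.intervals):
        raise InvalidParameterError("published slope count does not match interval count")
    rows = []
    for iv, pub in zip(table.intervals, published):
        rows.append(
            {
                "label": table.label,
                "t_start": iv.t_start,
                "t_end": iv.t_end,
                "raw_slope": iv.raw_slope,
                "rounded_slope": iv.rounded_slope,
                "published_slope": pub,
                "matches": round_half_away(iv.raw_slope, decimals) == pub,
            }
        )
    return pd.DataFrame(rows)
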