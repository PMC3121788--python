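"""Positional mapping of gene targets relative to the nuclear matrix.

Under limited DNase-I digestion, loop DNA is removed outside-in: distal
sequences are lost first, NM-proximal ones later, embedded ones never.
A target amplicon that is still PCR-amplifiable from NM-bound template
after t minutes of digestion therefore lies at least as close to the NM
as the topological zone bound to t.  The position call for an amplicon
is the innermost (longest-digestion) zone at which it is still positive.

Replicate detections are summarized with bench semantics: "+" when all
replicates amplified, "-" when none did, and the intermediate "±" when
at least one (but not every) replicate failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MonotonicityError
from .kinetics import ZoneScheme

__all__ = [
    "POSITIVE",
    "AMBIGUOUS",
    "NEGATIVE",
    "AmpliconScoreMatrix",
    "PositionCall",
    "MappingResult",
    "score_replicates",
    "call_position",
    "mapping_table",
    "positional_shift",
    "normalize_symbol",
]

POSITIVE = "+"
AMBIGUOUS = "±"
NEGATIVE = "-"

_SYMBOL_ALIASES = {
    "+": POSITIVE,
    "±": AMBIGUOUS,
    "+/-": AMBIGUOUS,
    "+-": AMBIGUOUS,
    "-": NEGATIVE,
    "−": NEGATIVE,  # U+2212 minus sign
}


def normalize_symbol(symbol: str) -> str:
    try:
        return _SYMBOL_ALIASES[symbol.strip()]
    except KeyError:
        raise InvalidParameterError(f"unknown detection symbol {symbol!r}") from None


def score_replicates(detections) -> str:
    """Collapse replicate booleans for one (amplicon, age, timepoint) cell."""
    det = [bool(d) for d in detections]
    if not det:
        raise InvalidParameterError("score_replicates: empty replicate set")
    if all(det):
        return POSITIVE
    if not any(det):
        return NEGATIVE
    return AMBIGUOUS


@dataclass
class AmpliconScoreMatrix:
    """Per-amplicon, per-timepoint, per-replicate PCR detection calls.

    ``entries`` columns: amplicon, age, timepoint_min, replicate, detected.
    """

    entries: pd.DataFrame

    _REQUIRED = ("amplicon", "age", "timepoint_min", "replicate", "detected")

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in self._REQUIRED if c not in df.columns]
        if missing:
            raise InvalidParameterError(f"score matrix missing columns: {missing}")
        if df.empty:
            raise InvalidParameterError("score matrix is empty")
        key = ["amplicon", "age", "timepoint_min", "replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise InvalidParameterError(f"duplicate replicate row for {first}")
        self.entries = df.reset_index(drop=True).assign(detected=df["detected"].astype(bool).values)

    @property
    def amplicons(self) -> tuple:
        return tuple(pd.unique(self.entries["amplicon"]))

    @property
    def ages(self) -> tuple:
        return tuple(pd.unique(self.entries["age"]))

    def replicate_counts(self) -> pd.DataFrame:
        return (
            self.entries.groupby(["amplicon", "age", "timepoint_min"], sort=False)["replicate"]
            .count()
            .rename("n_replicates")
            .reset_index()
        )

    def summary_symbols(self) -> pd.DataFrame:
        """Collapse replicates to +/±/- per (amplicon, age, timepoint)."""
        rows = []
        for (amp, age, tp), grp in self.entries.groupby(
            ["amplicon", "age", "timepoint_min"], sort=False
        ):
            rows.append(
                {
                    "amplicon": amp,
                    "age": age,
                    "timepoint_min": tp,
                    "symbol": score_replicates(grp["detected"].tolist()),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PositionCall:
    """Zone placement of one amplicon in one age group."""

    amplicon_name: str
    age_label: str
    zone: str
    distance_rank: int  # innermost zone = 1, increasing away from the NM
    ambiguous: bool  # call-determining symbol was ±
    violations: tuple = ()


def call_position(
    pattern,
    scheme: ZoneScheme,
    *,
    ambiguous_counts_positive: bool = True,
    amplicon_name: str = "",
    age_label: str = "",
) -> PositionCall:
    """Innermost-positive zone call for one positivity pattern.

    ``pattern`` lists one symbol per zone in the scheme's order
    (outermost first).  Outside-in digestion makes admissible patterns
    monotone: positives first, then negatives.  A negative followed
    inward by a positive, or a pattern with no positive at all, is a
    QC failure and raises :class:`MonotonicityError`.
    """
    symbols = [normalize_symbol(s) for s in pattern]
    labels = scheme.labels
    if len(symbols) != len(labels):
        raise InvalidParameterError(
            f"pattern length {len(symbols)} != zone count {len(labels)}"
        )
    positive = [
        s == POSITIVE or (s == AMBIGUOUS and ambiguous_counts_positive) for s in symbols
    ]
    seen_negative = False
    for lab, pos in zip(labels, positive):
        if not pos:
            seen_negative = True
        elif seen_negative:
            raise MonotonicityError(
                f"{amplicon_name or 'pattern'} {tuple(symbols)}: positive zone {lab} "
                "inward of a negative one is impossible under outside-in digestion"
            )
    if not any(positive):
        raise MonotonicityError(
            f"{amplicon_name or 'pattern'}: no positive zone; unscorable"
        )
    idx = max(i for i, pos in enumerate(positive) if pos)
    zone = labels[idx]
    return PositionCall(
        amplicon_name=amplicon_name,
        age_label=age_label,
        zone=zone,
        distance_rank=scheme.rank(zone),
        ambiguous=symbols[idx] == AMBIGUOUS,
    )


@dataclass
class MappingResult:
    """Position calls per (amplicon, age) plus rows that failed QC."""

    calls: pd.DataFrame
    failures: list = field(default_factory=list)

    def calls_for_age(self, age) -> pd.DataFrame:
        return self.calls[self.calls["age"] == age].reset_index(drop=True)


def _symbols_by_pair(summary: pd.DataFrame, scheme: ZoneScheme) -> dict:
    out = {}
    for (amp, age), grp in summary.groupby(["amplicon", "age"], sort=False):
        by_tp = dict(zip(grp["timepoint_min"], grp["symbol"]))
        missing = [t for t in scheme.timepoints if t not in by_tp]
        if missing:
            raise InvalidParameterError(
                f"({amp}, {age}): no scores for zone time points {missing}"
            )
        out[(amp, age)] = [by_tp[t] for t in scheme.timepoints]
    return out


def mapping_table(
    matrix,
    scheme: ZoneScheme,
    *,
    ambiguous_counts_positive: bool = True,
) -> MappingResult:
    """One position call per (amplicon, age) pair.

    ``matrix`` may be an :class:`AmpliconScoreMatrix` (replicates are
    collapsed first) or an already-summarized symbol table with columns
    amplicon/age/timepoint_min/symbol.  Per-row call failures are
    collected and reported; the remaining rows are still called.
    """
    if isinstance(matrix, AmpliconScoreMatrix):
        summary = matrix.summary_symbols()
    else:
        summary = matrix.copy()
        summary["symbol"] = summary["symbol"].map(normalize_symbol)
    rows, failures = [], []
    for (amp, age), symbols in _symbols_by_pair(summary, scheme).items():
        try:
            call = call_position(
                symbols,
                scheme,
                ambiguous_counts_positive=ambiguous_counts_positive,
                amplicon_name=amp,
                age_label=age,
            )
        except MonotonicityError as err:
            failures.append({"amplicon": amp, "age": age, "error": str(err)})
            continue
        rows.append(
            {
                "amplicon": amp,
                "age": age,
                "zone": call.zone,
                "distance_rank": call.distance_rank,
                "ambiguous": call.ambiguous,
                "pattern": "".join(symbols),
            }
        )
    columns = ["amplicon", "age", "zone", "distance_rank", "ambiguous", "pattern"]
    calls = pd.DataFrame(rows, columns=columns)
    return MappingResult(calls=calls, failures=failures)


def positional_shift(table_young: pd.DataFrame, table_old: pd.DataFrame) -> dict:
    """Per-amplicon zone movement between a young and an old call table.

    Positive Δrank means the amplicon moved away from the NM with age.
    Returns a dict with the per-amplicon frame and away/toward/unchanged
    counts plus the median shift.
    """
    young = table_young.set_index("amplicon")["distance_rank"]
    old = table_old.set_index("amplicon")["distance_rank"]
    if set(young.index) != set(old.index):
        raise InvalidParameterError(
            f"amplicon sets differ: {sorted(set(young.index) ^ set(old.index))}"
        )
    old = old.reindex(young.index)
    delta = (old - young).astype(int)
    frame = pd.DataFrame(
        {
            "amplicon": young.index,
            "rank_young": young.values,
            "rank_old": old.values,
            "delta_rank": delta.values,
        }
    ).reset_index(drop=True)
    return {
        "per_amplicon": frame,
        "away": int((delta > 0).sum()),
        "toward": int((delta < 0).sum()),
        "unchanged": int((delta == 0).sum()),
        "median_delta_rank": float(np.median(delta.values)),
    }
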