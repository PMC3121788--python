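"""Bundled reference data: rat cortical-neuron nucleoid measurements.

The package ships a small transcription of published measurements on
nucleoids from rat cerebral-cortex neurons at four post-natal ages
(P0 newborn, P7, P80 adult, P540 old):

* limited DNase-I digestion time courses (% NM-attached DNA at
  0/5/15/30/60 min) with the locally reported slopes;
* the PCR positivity table for nine gene-target amplicons across the
  four topological zones (D, P, VC, E) at each age;
* amplicon metadata (length, chromosome band, expression annotation);
* halo-derived average loop sizes (mean ± SD kbp, n = 50).

These fixtures let the whole analysis pipeline run with zero downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kinetics import DEFAULT_ZONE_LABELS, DigestionTimeCourse, ZoneBin, ZoneScheme

__all__ = [
    "AGE_GROUPS",
    "REFERENCE_LOCAL_SLOPES",
    "reference_timecourses",
    "reference_zone_scores",
    "reference_score_matrix_entries",
    "reference_amplicon_metadata",
    "reference_loop_sizes",
    "reference_zone_scheme",
]

AGE_GROUPS = ("P0", "P7", "P80", "P540")

# Locally reported digestion slopes (pct/min) per age over the intervals
# 0-5, 5-15, 15-30 and 30-60 min.  The P0 entries for 15-30 and 30-60 min
# are NOT the finite differences of the P0 percentages (recomputation
# gives -0.5 and -0.3); they are kept verbatim so the discrepancy is
# flagged by the analysis instead of silently repaired.
REFERENCE_LOCAL_SLOPES = {
    "P0": (-8.8, -3.1, -2.2, -3.4),
    "P7": (-10.2, -2.5, -0.3, -0.1),
    "P80": (-6.7, -2.9, -0.8, -0.3),
    "P540": (-4.7, -2.0, -0.7, -0.7),
}

# P0 intervals whose printed slope disagrees with the finite difference
# of the printed percentages, as (t_start, t_end) pairs.
KNOWN_SLOPE_DISCREPANCIES = {"P0": ((15.0, 30.0), (30.0, 60.0))}


def _read(name: str) -> pd.DataFrame:
    with resources.files("nmloops.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def reference_timecourses() -> dict:
    """Digestion time courses keyed by age group."""
    df = _read("neuron_digestion_timecourses.tsv")
    out = {}
    for age in AGE_GROUPS:
        sub = df[df["label"] == age]
        out[age] = DigestionTimeCourse.from_arrays(
            age,
            sub["time_min"].tolist(),
            sub["pct_attached"].tolist(),
            sub["sd"].tolist(),
            sub["n"].tolist(),
        )
    return out


def reference_zone_scores() -> pd.DataFrame:
    """Long-form PCR positivity symbols: amplicon, age, zone, symbol."""
    return _read("neuron_amplicon_zone_scores.tsv")


def reference_zone_scheme(timepoints=(5.0, 15.0, 30.0, 60.0)) -> ZoneScheme:
    """The standard four-zone scheme: D@5, P@15, VC@30, E@60 min."""
    return ZoneScheme(
        zones=tuple(
            ZoneBin(label=lab, timepoint_min=float(t))
            for lab, t in zip(DEFAULT_ZONE_LABELS, timepoints)
        )
    )


def reference_score_matrix_entries(n_replicates: int = 4) -> pd.DataFrame:
    """Replicate-expanded detection calls mirroring the symbol table.

    "+" becomes n/n positive, "-" 0/n, and "±" (n-1)/n — one failed
    experiment, the documented meaning of the intermediate symbol.
    Zone symbols are mapped to their digestion time points (D@5 ... E@60)
    and a t=0 control row (always positive) is added per replicate.
    """
    scheme = reference_zone_scheme()
    symbols = reference_zone_scores()
    rows = []
    for _, rec in symbols.iterrows():
        tp = scheme.timepoint_for(rec["zone"])
        for rep in range(n_replicates):
            if rec["symbol"] == "+":
                det = True
            elif rec["symbol"] == "±":
                det = rep != n_replicates - 1
            else:
                det = False
            rows.append(
                {
                    "amplicon": rec["amplicon"],
                    "age": rec["age"],
                    "timepoint_min": tp,
                    "replicate": rep,
                    "detected": det,
                }
            )
    for (amp, age) in symbols[["amplicon", "age"]].drop_duplicates().itertuples(index=False):
        for rep in range(n_replicates):
            rows.append(
                {
                    "amplicon": amp,
                    "age": age,
                    "timepoint_min": 0.0,
                    "replicate": rep,
                    "detected": True,
                }
            )
    return pd.DataFrame(rows)


def reference_amplicon_metadata() -> pd.DataFrame:
    """Gene-target amplicons used for positional mapping (metadata only)."""
    return _read("pcr_amplicons.tsv")


def reference_loop_sizes() -> pd.DataFrame:
    """Halo-derived average DNA-loop sizes (kbp) per age group."""
    return _read("neuron_loop_sizes.tsv")
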