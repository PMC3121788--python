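"""Tabular readers/writers and run configuration.

Dialects: UTF-8 throughout, tab-separated for .tsv, comma for .csv,
"." decimal point, no thousands separators.  Attached-DNA values are
stored as numbers on the 0-100 percent scale.  Validation happens at
load time and parse errors name the offending line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import InvalidParameterError, ParseError
from .halo import HaloMeasurementSet
from .kinetics import DigestionTimeCourse, ZoneBin, ZoneScheme
from .mapping import AmpliconScoreMatrix

__all__ = [
    "read_timecourses",
    "read_timecourse",
    "write_timecourses",
    "read_score_matrix",
    "write_score_matrix",
    "read_halo_measurements",
    "write_halo_measurements",
    "read_zone_scheme",
    "write_zone_scheme",
    "RunConfig",
    "EnsembleParams",
    "ProfileParams",
    "SimulationParams",
    "EvolveParams",
    "file_sha256",
]

_TC_COLUMNS = ["label", "time_min", "pct_attached", "sd", "n"]
_SCORE_COLUMNS = ["amplicon", "age", "timepoint_min", "replicate", "detected"]


def file_sha256(path) -> str:
    """Hex digest of a file, for provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header must be {required}")


def read_timecourses(path) -> dict:
    """All digestion time courses in a TSV, keyed by label.

    Enforces per label: strictly increasing times starting at 0,
    pct_attached in [0, 100] with 100.0 at t = 0.  Errors cite the
    1-based file line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ParseError(f"{path}: cannot parse TSV: {err}") from err
    _require_columns(df, _TC_COLUMNS, path)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    out = {}
    for label, sub in df.groupby("label", sort=False):
        lines = (sub.index + 2).tolist()  # +1 header, +1 1-based
        prev_t = None
        for line_no, (_, row) in zip(lines, sub.iterrows()):
            t, pct = row["time_min"], row["pct_attached"]
            if prev_t is not None and t <= prev_t:
                raise ParseError(
                    f"{path}, line {line_no}: time {t} not after previous {prev_t} "
                    f"for label {label!r}"
                )
            if not (0.0 <= pct <= 100.0):
                raise ParseError(
                    f"{path}, line {line_no}: pct_attached {pct} outside [0, 100]"
                )
            prev_t = t
        first = sub.iloc[0]
        if first["time_min"] != 0 or first["pct_attached"] != 100.0:
            raise ParseError(
                f"{path}, line {lines[0]}: label {label!r} must start at "
                "t=0 with pct_attached=100.0"
            )
        out[label] = DigestionTimeCourse.from_arrays(
            label,
            sub["time_min"].tolist(),
            sub["pct_attached"].tolist(),
            sub["sd"].tolist(),
            sub["n"].fillna(1).astype(int).tolist(),
        )
    return out


def read_timecourse(path, label: str | None = None) -> DigestionTimeCourse:
    """A single validated time course; `label` is required if several are present."""
    courses = read_timecourses(path)
    if label is not None:
        if label not in courses:
            raise ParseError(f"{path}: no time course labelled {label!r}")
        return courses[label]
    if len(courses) != 1:
        raise ParseError(
            f"{path}: contains {sorted(courses)}; pass label= to pick one"
        )
    return next(iter(courses.values()))


def write_timecourses(path, courses) -> None:
    """Write one or several time courses; read_timecourses round-trips."""
    if isinstance(courses, DigestionTimeCourse):
        courses = [courses]
    frames = [tc.to_frame() for tc in courses]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_score_matrix(path) -> AmpliconScoreMatrix:
    """Replicate-level PCR detection calls from a TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as err:
        raise ParseError(f"{path}: file is empty") from err
    except Exception as err:
        raise ParseError(f"{path}: cannot parse TSV: {err}") from err
    _require_columns(df, _SCORE_COLUMNS, path)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    key = ["amplicon", "age", "timepoint_min", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}, line {line}: duplicate (amplicon, age, timepoint, replicate)")
    try:
        return AmpliconScoreMatrix(entries=df[_SCORE_COLUMNS + [c for c in df.columns if c not in _SCORE_COLUMNS]])
    except InvalidParameterError as err:
        raise ParseError(f"{path}: {err}") from err


def write_score_matrix(path, matrix: AmpliconScoreMatrix) -> None:
    matrix.entries.to_csv(path, sep="\t", index=False)


def read_halo_measurements(path) -> dict:
    """Halo/nucleus/NM morphometry CSV -> HaloMeasurementSet per label."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: cannot parse CSV: {err}") from err
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing 'label' column")
    out = {}
    for label, sub in df.groupby("label", sort=False):
        try:
            out[label] = HaloMeasurementSet(
                label=label, records=sub.drop(columns=["label"]).reset_index(drop=True)
            )
        except InvalidParameterError as err:
            raise ParseError(f"{path}: {err}") from err
    return out


def write_halo_measurements(path, sets) -> None:
    frames = [s.records.assign(label=s.label) for s in sets]
    df = pd.concat(frames, ignore_index=True)
    cols = ["label"] + [c for c in df.columns if c != "label"]
    df[cols].to_csv(path, index=False)


def read_zone_scheme(path) -> ZoneScheme:
    """Zone scheme TSV with columns zone, timepoint_min (outermost first)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["zone", "timepoint_min"], path)
    return ZoneScheme(
        zones=tuple(
            ZoneBin(label=str(r["zone"]), timepoint_min=float(r["timepoint_min"]))
            for _, r in df.iterrows()
        )
    )


def write_zone_scheme(path, scheme: ZoneScheme) -> None:
    pd.DataFrame(
        {"zone": list(scheme.labels), "timepoint_min": list(scheme.timepoints)}
    ).to_csv(path, sep="\t", index=False)


# -- run configuration --------------------------------------------------------

@dataclass
class EnsembleParams:
    n_loops: int = 1000
    mean_kbp: float = 42.0
    cv: float = 0.1
    embedded_target: float = 0.02


@dataclass
class ProfileParams:
    k0: float = 2.0e-4
    alpha: float = 2.0


@dataclass
class SimulationParams:
    timepoints_min: tuple = (0.0, 5.0, 15.0, 30.0, 60.0)
    n_nucleoids: int = 10_000
    n_nucleoids_timecourse: int = 200
    n_replicates: int = 4
    detection_threshold: float = 1e-3
    dnase_u_per_ml: float = 0.92


@dataclass
class EvolveParams:
    mode: str = "B_extension"
    extension_fraction: float = 0.1
    p_sub: float = 1.0
    sub_mean_kbp: float = 42.0
    sub_cv: float = 0.1


@dataclass
class RunConfig:
    """Full pipeline parameterization; serializes losslessly to YAML."""

    ensemble: EnsembleParams = field(default_factory=EnsembleParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    evolve: EvolveParams = field(default_factory=EvolveParams)
    master_seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    _SECTIONS = {
        "ensemble": EnsembleParams,
        "profile": ProfileParams,
        "simulation": SimulationParams,
        "evolve": EvolveParams,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for key in list(data):
            if key in cls._SECTIONS:
                section_cls = cls._SECTIONS[key]
                section = dict(data.pop(key) or {})
                names = {f.name for f in dataclasses.fields(section_cls)}
                unknown = sorted(set(section) - names)
                if unknown:
                    raise InvalidParameterError(
                        f"unknown config key {key}.{unknown[0]!r}"
                    )
                if "timepoints_min" in section:
                    section["timepoints_min"] = tuple(section["timepoints_min"])
                kwargs[key] = section_cls(**section)
        top_names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - top_names)
        if unknown:
            raise InvalidParameterError(f"unknown config key {unknown[0]!r}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["timepoints_min"] = list(d["simulation"]["timepoints_min"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
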