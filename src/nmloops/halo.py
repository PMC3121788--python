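"""DNA-halo quantification and group statistics.

When a nucleoid is exposed to a saturating concentration of an
intercalator (ethidium bromide), the supercoiled loops unwind into a
fluorescent halo around the nuclear matrix (NM).  The maximum halo
radius R tracks the average loop size: a loop is an out-and-back path of
B-DNA, so a halo of radius R µm corresponds to roughly

    loop_kbp = 2 * R * 1000 / rise_nm_per_bp / 1000

with the canonical B-DNA rise of 0.34 nm/bp by default.  The conversion
constant is exposed because published halo→kbp calibrations differ.

Group comparisons use the two-sample Student's t-test (pooled variance
by default, Welch by flag), matching the convention for equal-n
morphometric samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "HaloMeasurementSet",
    "LoopSizeEstimate",
    "TTestResult",
    "loop_size_from_halo",
    "summarize_measurements",
    "students_t_test",
    "nm_resilience",
    "loop_size_estimate",
    "B_DNA_RISE_NM_PER_BP",
]

B_DNA_RISE_NM_PER_BP = 0.34

_FIELDS = ("nucleus_diameter_um", "nm_diameter_um", "halo_radius_um")


@dataclass
class HaloMeasurementSet:
    """Per-nucleoid morphometry for one age group (units: µm)."""

    label: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        present = [c for c in _FIELDS if c in df.columns]
        if not present:
            raise InvalidParameterError(
                f"measurement set {self.label!r} has none of the expected fields {_FIELDS}"
            )
        for c in present:
            vals = df[c].dropna()
            if (vals <= 0).any():
                raise InvalidParameterError(f"{self.label}: non-positive values in {c}")
        self.records = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.records)

    def column(self, field: str) -> np.ndarray:
        if field not in self.records.columns:
            raise InvalidParameterError(f"{self.label}: field {field!r} missing")
        return self.records[field].dropna().to_numpy(dtype=float)


@dataclass(frozen=True)
class LoopSizeEstimate:
    label: str
    mean_kbp: float
    sd_kbp: float
    rise_nm_per_bp: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float
    significant: bool
    variant: str


def loop_size_from_halo(radius_um, rise_nm_per_bp: float = B_DNA_RISE_NM_PER_BP):
    """Average loop size (kbp) deduced from a maximum halo radius (µm).

    Linear and strictly monotone in the radius; exact inverse of the
    noise-free halo simulator.
    """
    radius = np.asarray(radius_um, dtype=float)
    if np.any(radius < 0):
        raise InvalidParameterError("halo radius must be >= 0")
    if rise_nm_per_bp <= 0:
        raise InvalidParameterError("rise_nm_per_bp must be > 0")
    kbp = 2.0 * radius * 1000.0 / rise_nm_per_bp / 1000.0
    return float(kbp) if np.isscalar(radius_um) else kbp


def summarize_measurements(measurements: HaloMeasurementSet) -> pd.DataFrame:
    """Sample mean ± SD (n-1 denominator) per measured field."""
    rows = []
    for field in _FIELDS:
        if field not in measurements.records.columns:
            continue
        vals = measurements.column(field)
        if len(vals) < 2:
            raise InvalidParameterError(
                f"{measurements.label}: need n >= 2 for SD of {field}"
            )
        rows.append(
            {
                "label": measurements.label,
                "field": field,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def students_t_test(
    sample_a, sample_b, alpha: float = 0.01, variant: str = "pooled"
) -> TTestResult:
    """Two-sample t-test; ``variant`` is "pooled" (Student) or "welch"."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise InvalidParameterError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    equal_var = variant == "pooled"
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            # degenerate but well-defined: identical constant samples
            df = len(a) + len(b) - 2
            return TTestResult(0.0, float(df), 1.0, alpha, False, variant)
        raise InvalidParameterError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(len(a) + len(b) - 2)
    else:
        na, nb = len(a), len(b)
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = float(num / den)
    p = float(res.pvalue)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        variant=variant,
    )


def nm_resilience(measurements: HaloMeasurementSet) -> dict:
    """Is the NM wider than the nucleus it came from (a resilient matrix)?"""
    nm = measurements.column("nm_diameter_um")
    nucleus = measurements.column("nucleus_diameter_um")
    if len(nm) == 0 or len(nucleus) == 0:
        raise InvalidParameterError("both nucleus and NM diameters are required")
    ratio = float(np.mean(nm) / np.mean(nucleus))
    return {"ratio": ratio, "resilient": ratio > 1.0}


def loop_size_estimate(
    measurements: HaloMeasurementSet, rise_nm_per_bp: float = B_DNA_RISE_NM_PER_BP
) -> LoopSizeEstimate:
    """Per-group loop-size estimate from the halo radius samples."""
    radii = measurements.column("halo_radius_um")
    if len(radii) < 1:
        raise InvalidParameterError(f"{measurements.label}: no halo radii")
    kbp = loop_size_from_halo(radii, rise_nm_per_bp)
    sd = float(np.std(kbp, ddof=1)) if len(radii) > 1 else math.nan
    return LoopSizeEstimate(
        label=measurements.label,
        mean_kbp=float(np.mean(kbp)),
        sd_kbp=sd,
        rise_nm_per_bp=rise_nm_per_bp,
        n=len(radii),
    )
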