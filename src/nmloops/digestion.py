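"""Monte-Carlo and analytic models of limited DNase-I nucleoid digestion.

Each loop of total length L bp carries MAR footprints of zero hazard at
both anchors; the free span in between is cleaved by a non-homogeneous
Poisson process with per-bp hazard ``k0 * a(d(u))``, where ``u`` is the
arc fraction along the loop, ``d(u) = min(u, 1 - u)`` and
``a(d) = (2 d)**alpha`` (see :class:`~nmloops.types.AccessibilityProfile`).
A fragment produced by the cuts stays NM-attached iff it still contains
part of a MAR footprint; with anchors at both ends these are exactly the
leftmost and rightmost fragments.  Distal (apex-ward) DNA is therefore
lost first and anchor-proximal DNA last, and the MAR footprints
themselves — the embedded, non-digestible fraction — are never lost.

The per-position survival-attached probability has a closed integral
form: a position at arc fraction u is still on an attached fragment at
time t with probability

    exp(-H(base_L, u)) + exp(-H(u, base_R)) - exp(-H(base_L, base_R))

where H(x, y) is the cumulative cut hazard accrued on (x, y) by time t
(inclusion–exclusion over "no cut between u and either anchor").  The
analytic expectation integrates this over the loop and serves as the
exact oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .errors import InvalidParameterError
from .kinetics import DigestionTimeCourse
from .mapping import AmpliconScoreMatrix
from .types import AccessibilityProfile, Amplicon, Loop, NucleoidModel, SimulationConfig

__all__ = [
    "accessibility_cdf",
    "accessibility_ppf",
    "analytic_attached_fraction",
    "analytic_amplicon_survival",
    "simulate_digestion",
    "simulate_amplicon_detection",
    "DigestionResult",
    "design_zone_probes",
]


# -- accessibility-profile integrals -----------------------------------------

def accessibility_cdf(u, alpha: float):
    """A(u) = ∫_0^u a(d(s)) ds with a(d) = (2 d)**alpha, d = min(s, 1-s).

    A(1) = 1 / (alpha + 1); symmetric about u = 0.5.
    """
    u = np.asarray(u, dtype=float)
    ap1 = alpha + 1.0
    lower = (2.0 * np.minimum(u, 0.5)) ** ap1 / (2.0 * ap1)
    upper = 1.0 / ap1 - (2.0 * np.minimum(1.0 - u, 0.5)) ** ap1 / (2.0 * ap1)
    return np.where(u <= 0.5, lower, upper)


def accessibility_ppf(c, alpha: float):
    """Inverse of :func:`accessibility_cdf` on [0, A(1)] (exact, no rejection)."""
    c = np.asarray(c, dtype=float)
    ap1 = alpha + 1.0
    half = 0.5 / ap1  # A(0.5)
    c_low = np.clip(c, 0.0, half)
    u_low = 0.5 * (2.0 * ap1 * c_low) ** (1.0 / ap1)
    c_high = np.clip(1.0 / ap1 - c, 0.0, half)
    u_high = 1.0 - 0.5 * (2.0 * ap1 * c_high) ** (1.0 / ap1)
    return np.where(c <= half, u_low, u_high)


def _free_span(loop: Loop) -> tuple:
    """(u_left, u_right): arc fractions bounding the nuclease-exposed span."""
    L = loop.total_bp
    return loop.left_footprint_bp / L, 1.0 - loop.right_footprint_bp / L


def _hazard_scale(loop: Loop, profile: AccessibilityProfile, t: float) -> float:
    """Multiplier turning an accessibility-CDF increment into cut counts."""
    return t * profile.k0 * loop.total_bp


# -- analytic oracle ----------------------------------------------------------

def analytic_attached_fraction(loop: Loop, profile: AccessibilityProfile, t: float) -> float:
    """Expected NM-attached DNA mass fraction of one loop at time t.

    Numerical integration of the per-position survival-attached
    probability over the free span (relative tolerance well below 1e-6);
    MAR footprint mass is always attached.
    """
    if t < 0:
        raise InvalidParameterError(f"time must be >= 0, got {t}")
    ul, ur = _free_span(loop)
    if t == 0 or profile.k0 == 0 or ur <= ul:
        return 1.0
    scale = _hazard_scale(loop, profile, t)
    a_ul = float(accessibility_cdf(ul, profile.alpha))
    a_ur = float(accessibility_cdf(ur, profile.alpha))
    h_total = scale * (a_ur - a_ul)

    def survival(u):
        a_u = accessibility_cdf(u, profile.alpha)
        return (
            np.exp(-scale * (a_u - a_ul))
            + np.exp(-scale * (a_ur - a_u))
            - math.exp(-h_total)
        )

    interior = [p for p in (0.5,) if ul < p < ur]
    integral, _ = integrate.quad(
        survival, ul, ur, points=interior, epsabs=1e-12, epsrel=1e-9, limit=200
    )
    return (ul + (1.0 - ur)) + integral


def analytic_amplicon_survival(
    loop: Loop, profile: AccessibilityProfile, amplicon: Amplicon, t: float
) -> float:
    """P(amplicon interval is uncut AND on an NM-attached fragment) at time t.

    The interval survives iff there is no cut between the left anchor
    and its right edge, or none between its left edge and the right
    anchor (either way it is both intact and anchored).
    """
    if t < 0:
        raise InvalidParameterError(f"time must be >= 0, got {t}")
    L = loop.total_bp
    if not (0 <= amplicon.start_bp and amplicon.end_bp <= L):
        raise InvalidParameterError(
            f"amplicon {amplicon.name} interval outside loop {loop.loop_id}"
        )
    ul, ur = _free_span(loop)
    if t == 0 or profile.k0 == 0 or ur <= ul:
        return 1.0
    s = min(max(amplicon.start_bp / L, ul), ur)
    e = min(max(amplicon.end_bp / L, ul), ur)
    scale = _hazard_scale(loop, profile, t)
    a = lambda u: float(accessibility_cdf(u, profile.alpha))
    h_left = scale * (a(e) - a(ul))  # cuts between left anchor and right edge
    h_right = scale * (a(ur) - a(s))
    h_total = scale * (a(ur) - a(ul))
    return math.exp(-h_left) + math.exp(-h_right) - math.exp(-h_total)


# -- Monte-Carlo sampler ------------------------------------------------------

def _sample_cuts(rng, loop: Loop, profile: AccessibilityProfile, t_max: float, n: int):
    """Draw the cut process for `n` independent nucleoid copies of one loop.

    Each cut gets a position (bp, via exact inverse-CDF sampling from the
    accessibility density restricted to the free span) and an i.i.d.
    uniform cut time on [0, t_max]; thinning by time yields the process
    at any earlier time point, which makes per-nucleoid attached mass
    monotone in t by construction.
    """
    ul, ur = _free_span(loop)
    if ur <= ul or profile.k0 == 0 or t_max == 0:
        empty = np.empty(0)
        return np.empty(0, dtype=np.int64), empty, empty
    a_ul = float(accessibility_cdf(ul, profile.alpha))
    a_ur = float(accessibility_cdf(ur, profile.alpha))
    lam = _hazard_scale(loop, profile, t_max) * (a_ur - a_ul)
    counts = rng.poisson(lam, n)
    m = int(counts.sum())
    c = a_ul + rng.random(m) * (a_ur - a_ul)
    pos_bp = accessibility_ppf(c, profile.alpha) * loop.total_bp
    times = rng.random(m) * t_max
    idx = np.repeat(np.arange(n), counts)
    return idx, pos_bp, times


def _attached_mass(loop: Loop, idx, pos_bp, times, t: float, n: int):
    """Per-nucleoid NM-attached DNA mass (bp) of one loop at time t."""
    L = loop.total_bp
    active = times <= t
    ai, ap = idx[active], pos_bp[active]
    cnt = np.bincount(ai, minlength=n)
    first = np.full(n, L)
    np.minimum.at(first, ai, ap)
    last = np.zeros(n)
    np.maximum.at(last, ai, ap)
    return np.where(cnt == 0, L, first + (L - last))


@dataclass
class DigestionResult:
    """Simulated digestion: summary time course plus per-nucleoid detail."""

    timecourse: DigestionTimeCourse
    per_nucleoid_pct: np.ndarray  # shape (n_timepoints, n_nucleoids)
    cut_counts: pd.DataFrame  # per (loop, timepoint) mean cut count


def simulate_digestion(
    model: NucleoidModel,
    config: SimulationConfig,
    *,
    label: str = "sim",
    rng=None,
) -> DigestionResult:
    """Monte-Carlo digestion of the whole ensemble.

    Every simulated nucleoid carries one copy of each loop.  Reported
    values are 100 × attached mass / total mass, averaged over
    ``config.n_nucleoids`` nucleoids, with the across-nucleoid sample SD.
    The absorbed (NM-merged) mass of an evolved model always counts as
    attached.
    """
    if not model.loops:
        raise InvalidParameterError("cannot digest an empty model")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    tps = config.timepoints_min
    n = config.n_nucleoids
    t_max = tps[-1]
    total = model.total_bp
    attached = np.zeros((len(tps), n))
    attached += model.absorbed_bp
    cut_rows = []
    for loop in model.loops:
        idx, pos, times = _sample_cuts(rng, loop, model.profile, t_max, n)
        for k, t in enumerate(tps):
            attached[k] += _attached_mass(loop, idx, pos, times, t, n)
            cut_rows.append(
                {
                    "loop_id": loop.loop_id,
                    "time_min": t,
                    "mean_cuts": float((times <= t).sum()) / n,
                }
            )
    pct = 100.0 * attached / total
    means = pct.mean(axis=1)
    sds = pct.std(axis=1, ddof=1) if n > 1 else np.full(len(tps), math.nan)
    means[0], sds[0] = 100.0, 0.0  # t = 0: everything attached by construction
    tc = DigestionTimeCourse.from_arrays(label, tps, means, sds, [n] * len(tps))
    return DigestionResult(
        timecourse=tc, per_nucleoid_pct=pct, cut_counts=pd.DataFrame(cut_rows)
    )


def simulate_amplicon_detection(
    model: NucleoidModel,
    amplicons,
    config: SimulationConfig,
    *,
    age_label: str = "sim",
) -> AmpliconScoreMatrix:
    """Replicate PCR detection of amplicons across the digestion series.

    Per replicate (independent seed substream) and time point, an
    amplicon is detected iff the fraction of nucleoids in which its
    interval is uncut and NM-attached reaches ``detection_threshold``.
    Only the loops that carry amplicons are simulated.  An amplicon
    whose loop was absorbed into the NM by evolution is embedded and
    always detected.
    """
    loop_ids = {lp.loop_id for lp in model.loops}
    by_loop: dict = {}
    absorbed = []
    for amp in amplicons:
        if amp.loop_id in loop_ids:
            by_loop.setdefault(amp.loop_id, []).append(amp)
        elif amp.loop_id in model.absorbed_loop_ids:
            absorbed.append(amp)
        else:
            raise InvalidParameterError(
                f"amplicon {amp.name} references unknown loop {amp.loop_id!r}"
            )
    tps = config.timepoints_min
    n = config.n_nucleoids
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        for loop_id, amps in by_loop.items():
            loop = model.loop_by_id(loop_id)
            for amp in amps:
                if amp.end_bp > loop.total_bp:
                    raise InvalidParameterError(
                        f"amplicon {amp.name} extends past loop {loop_id}"
                    )
            idx, pos, times = _sample_cuts(rng, loop, model.profile, tps[-1], n)
            for t in tps:
                active = times <= t
                ai, ap = idx[active], pos[active]
                for amp in amps:
                    left_cuts = np.bincount(ai[ap < amp.end_bp], minlength=n)
                    right_cuts = np.bincount(ai[ap > amp.start_bp], minlength=n)
                    frac = float(((left_cuts == 0) | (right_cuts == 0)).mean())
                    rows.append(
                        {
                            "amplicon": amp.name,
                            "age": age_label,
                            "timepoint_min": t,
                            "replicate": rep,
                            "detected": frac >= config.detection_threshold,
                            "survival_fraction": frac,
                        }
                    )
        for amp in absorbed:
            for t in tps:
                rows.append(
                    {
                        "amplicon": amp.name,
                        "age": age_label,
                        "timepoint_min": t,
                        "replicate": rep,
                        "detected": True,
                        "survival_fraction": 1.0,
                    }
                )
    return AmpliconScoreMatrix(entries=pd.DataFrame(rows))


# -- planted-probe design -----------------------------------------------------

def design_zone_probes(
    model: NucleoidModel,
    scheme_timepoints,
    zone_assignment,
    *,
    length_bp: float = 250.0,
    survival_target: float = 0.01,
    embedded_target_survival: float = 0.05,
    threshold: float = 1e-3,
) -> tuple:
    """Plant one probe amplicon per requested zone on distinct loops.

    For a zone bound to time point t_z, the probe position is solved by
    bisection so that its analytic survival at t_z equals
    ``survival_target`` — comfortably above the detection threshold —
    while the near-exponential decay of survival in time pushes it far
    below threshold by the next time point.  Probes for the innermost
    (embedded) zone are placed just outside the MAR footprint where they
    survive the full series (analytic survival
    ``embedded_target_survival`` at the last time point).

    ``zone_assignment`` maps probe names to zone labels ordered
    outermost-first in ``scheme_timepoints`` (label -> timepoint).
    Returns (amplicons, truth) where truth maps probe name -> zone.
    Raises if the design margins cannot be met on the host loops.
    """
    labels = list(scheme_timepoints)
    tps = [scheme_timepoints[lab] for lab in labels]
    hosts = sorted(model.loops, key=lambda lp: lp.loop_id)
    if len(zone_assignment) > len(hosts):
        raise InvalidParameterError("more probes requested than loops available")
    amplicons, truth = [], {}
    for (name, zone), loop in zip(zone_assignment.items(), hosts):
        if zone not in labels:
            raise InvalidParameterError(f"unknown zone {zone!r}")
        innermost = zone == labels[-1]
        t_zone = scheme_timepoints[zone]
        target = embedded_target_survival if innermost else survival_target
        t_ref = tps[-1] if innermost else t_zone
        apex = 0.5 * loop.total_bp - length_bp / 2

        def surv_at(start_bp, t):
            probe = Amplicon(name=name, loop_id=loop.loop_id, start_bp=start_bp,
                             length_bp=length_bp)
            return analytic_amplicon_survival(loop, model.profile, probe, t)

        lo = loop.left_footprint_bp  # most protected placement
        hi = apex
        if surv_at(hi, t_ref) > target:
            raise InvalidParameterError(
                f"probe {name}: hazard too weak to reach survival {target} at apex"
            )
        start = float(optimize.brentq(lambda s: surv_at(s, t_ref) - target, lo, hi,
                                      xtol=1e-3))
        amp = Amplicon(name=name, loop_id=loop.loop_id, start_bp=start,
                       length_bp=length_bp)
        # design margins: solidly detectable at every zone up to (and at)
        # the probe's own zone, and negligible beyond it.  With a
        # threshold at or above the survival target no placement can be
        # robust; the margins are then moot (detection fails downstream).
        margins_checkable = 5 * threshold <= target
        for lab, t in zip(labels, tps):
            if not margins_checkable:
                break
            s = analytic_amplicon_survival(loop, model.profile, amp, t)
            inward_of_zone = tps.index(t) > labels.index(zone)
            if not inward_of_zone and s < 5 * threshold:
                raise InvalidParameterError(
                    f"probe {name}: survival {s:.2e} at t={t} too close to threshold"
                )
            if inward_of_zone and s > threshold / 5:
                raise InvalidParameterError(
                    f"probe {name}: residual survival {s:.2e} at t={t} may misclassify"
                )
        amplicons.append(amp)
        truth[name] = zone
    return amplicons, truth
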