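"""Building, aging and exporting nucleoid loop ensembles.

The builder draws loop sizes from a lognormal distribution specified by
its mean and coefficient of variation and splits the target embedded
(NM-buried) fraction equally between the two MAR anchors of every loop.

Two competing loop-rearrangement models describe how the nuclear
higher-order structure ages:

* **A (MAR substitution)** — some anchors detach and other, previously
  latent MARs take over: affected loops are re-drawn from a configured
  size distribution and gene positions within them are effectively
  randomized.
* **B (MAR extension)** — existing anchors grow, absorbing adjacent
  free loop DNA into the NM: the embedded fraction rises, loops whose
  free span vanishes are merged into the NM (fewer loops), and the
  sizes of surviving loops are untouched.  DNA mass is conserved
  exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InvalidParameterError
from .halo import HaloMeasurementSet
from .types import (
    AccessibilityProfile,
    Amplicon,
    Loop,
    MatrixAttachmentRegion,
    NucleoidModel,
)

__all__ = [
    "loop_size_distribution",
    "build_nucleoid_ensemble",
    "evolve_nhos",
    "simulate_halo_radii",
    "export_fixture",
    "import_fixture",
]


def loop_size_distribution(mean_kbp: float, cv: float):
    """Frozen lognormal over loop size in bp, parameterized by mean and CV."""
    if mean_kbp <= 0:
        raise InvalidParameterError("mean_kbp must be > 0")
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    mean_bp = mean_kbp * 1000.0
    if cv == 0:
        # degenerate point mass; callers special-case sampling
        return None
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean_bp) - sigma2 / 2.0
    return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))


def _draw_sizes(rng, n: int, mean_kbp: float, cv: float) -> np.ndarray:
    dist = loop_size_distribution(mean_kbp, cv)
    if dist is None:
        return np.full(n, round(mean_kbp * 1000.0))
    sizes = dist.rvs(size=n, random_state=rng)
    return np.maximum(np.round(sizes), 1.0)


def build_nucleoid_ensemble(
    n_loops: int,
    mean_kbp: float,
    cv: float,
    embedded_target: float,
    profile: AccessibilityProfile,
    seed: int,
    *,
    id_prefix: str = "loop",
) -> NucleoidModel:
    """Draw a reproducible loop ensemble with a target embedded fraction.

    Each loop's MAR footprints take ``embedded_target`` of its own
    length, split equally between the two anchors, so the realized
    ensemble embedded fraction equals the target exactly.
    """
    if n_loops < 1:
        raise InvalidParameterError("n_loops must be >= 1")
    if not (0.0 <= embedded_target < 1.0):
        raise InvalidParameterError("embedded_target must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sizes = _draw_sizes(rng, n_loops, mean_kbp, cv)
    width = len(str(n_loops))
    loops = []
    for i, total in enumerate(sizes):
        loop_id = f"{id_prefix}{i:0{width}d}"
        foot = embedded_target * float(total) / 2.0
        loops.append(
            Loop(
                loop_id=loop_id,
                total_bp=float(total),
                mars=(
                    MatrixAttachmentRegion(loop_id, "left", foot),
                    MatrixAttachmentRegion(loop_id, "right", foot),
                ),
            )
        )
    return NucleoidModel(loops=loops, profile=profile, seed=seed)


# -- aging operators ----------------------------------------------------------

def _extension_draw(rng, spec: dict, free_bp: float) -> float:
    kind = spec.get("kind", "fixed_fraction")
    if kind == "fixed_fraction":
        return spec.get("fraction", 0.1) * free_bp
    if kind == "exponential":
        if "mean_fraction" in spec:
            return float(rng.exponential(spec["mean_fraction"] * free_bp))
        return float(rng.exponential(spec["mean_bp"]))
    if kind == "fixed_bp":
        return float(spec["bp"])
    raise InvalidParameterError(f"unknown extension kind {kind!r}")


def evolve_nhos(
    model: NucleoidModel,
    mode: str,
    *,
    p_sub: float | None = None,
    loop_size_dist: tuple | None = None,
    extension: dict | float | None = None,
    seed: int = 0,
    amplicons=None,
):
    """Age the nuclear higher-order structure under model A or B.

    mode "A_substitution": each loop independently re-anchors with
    probability ``p_sub``; its size is re-drawn from
    ``loop_size_dist = (mean_kbp, cv)`` (per-side footprint fractions
    preserved) and any amplicon it hosts is re-placed uniformly within
    the new free span (the new anchors land at random positions relative
    to the fixed genomic offset of the gene).

    mode "B_extension": every MAR footprint grows by a draw from
    ``extension`` (default: deterministic 10% of the loop's free DNA per
    anchor), clipped so free DNA never goes negative; a loop whose free
    span vanishes is merged into the NM.  Total DNA mass is conserved
    exactly.

    Returns the evolved model, or ``(model, amplicons)`` when amplicons
    are supplied.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    amps_by_loop: dict = {}
    for amp in amplicons or ():
        amps_by_loop.setdefault(amp.loop_id, []).append(amp)
    new_amplicons = []

    if mode in ("A", "A_substitution"):
        if p_sub is None or loop_size_dist is None:
            raise InvalidParameterError("mode A needs p_sub and loop_size_dist")
        if not (0.0 <= p_sub <= 1.0):
            raise InvalidParameterError("p_sub must be in [0, 1]")
        mean_kbp, cv = loop_size_dist
        new_loops = []
        for loop in model.loops:
            if rng.random() < p_sub:
                total = float(_draw_sizes(rng, 1, mean_kbp, cv)[0])
                frac_l = loop.left_footprint_bp / loop.total_bp
                frac_r = loop.right_footprint_bp / loop.total_bp
                new_loop = Loop(
                    loop_id=loop.loop_id,
                    total_bp=total,
                    mars=(
                        MatrixAttachmentRegion(loop.loop_id, "left", frac_l * total),
                        MatrixAttachmentRegion(loop.loop_id, "right", frac_r * total),
                    ),
                )
                for amp in amps_by_loop.get(loop.loop_id, ()):
                    lo = new_loop.left_footprint_bp
                    hi = max(total - new_loop.right_footprint_bp - amp.length_bp, lo)
                    start = float(rng.uniform(lo, hi))
                    new_amplicons.append(
                        Amplicon(amp.name, amp.loop_id, start, amp.length_bp,
                                 amp.chromosome_label, amp.expressed)
                    )
            else:
                new_loop = loop
                new_amplicons.extend(amps_by_loop.get(loop.loop_id, ()))
            new_loops.append(new_loop)
        evolved = NucleoidModel(
            loops=new_loops,
            profile=model.profile,
            seed=model.seed,
            absorbed_bp=model.absorbed_bp,
            absorbed_loop_ids=set(model.absorbed_loop_ids),
        )
        return (evolved, new_amplicons) if amplicons is not None else evolved

    if mode in ("B", "B_extension"):
        if extension is None:
            extension = {"kind": "fixed_fraction", "fraction": 0.1}
        if isinstance(extension, (int, float)):
            extension = {"kind": "fixed_fraction", "fraction": float(extension)}
        new_loops = []
        absorbed_bp = model.absorbed_bp
        absorbed_ids = set(model.absorbed_loop_ids)
        for loop in model.loops:
            free = loop.free_bp
            e_l = max(_extension_draw(rng, extension, free), 0.0)
            e_r = max(_extension_draw(rng, extension, free), 0.0)
            growth = e_l + e_r
            if growth > free:  # clip, never negative free DNA
                scale = free / growth if growth > 0 else 0.0
                e_l, e_r = e_l * scale, e_r * scale
            new_loop = loop.with_footprints(
                loop.left_footprint_bp + e_l, loop.right_footprint_bp + e_r
            )
            if new_loop.is_fully_embedded:
                absorbed_bp += new_loop.total_bp
                absorbed_ids.add(new_loop.loop_id)
            else:
                new_loops.append(new_loop)
                new_amplicons.extend(amps_by_loop.get(loop.loop_id, ()))
        for loop_id in absorbed_ids - set(model.absorbed_loop_ids):
            new_amplicons.extend(amps_by_loop.get(loop_id, ()))
        evolved = NucleoidModel(
            loops=new_loops,
            profile=model.profile,
            seed=model.seed,
            absorbed_bp=absorbed_bp,
            absorbed_loop_ids=absorbed_ids,
        )
        return (evolved, new_amplicons) if amplicons is not None else evolved

    raise InvalidParameterError(f"unknown mode {mode!r}")


# -- halo emission ------------------------------------------------------------

def simulate_halo_radii(
    model: NucleoidModel,
    n: int,
    noise_cv: float,
    rise_nm_per_bp: float = 0.34,
    seed: int = 0,
    *,
    label: str = "sim",
    nucleus_diameter_um: float = 10.0,
    nm_diameter_um: float = 11.0,
) -> HaloMeasurementSet:
    """Emit noisy per-nucleoid halo radii consistent with the loop ensemble.

    The noise-free radius is (mean free loop length in bp × rise / 1000)
    / 2 µm (a loop unwinds out and back); measurement noise is
    multiplicative Gaussian with the given CV.  Nucleus and NM diameters
    get the same relative noise around their configured means (NM wider
    than nucleus by default: a resilient matrix).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if not model.loops:
        raise InvalidParameterError("cannot measure halos of an empty model")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean_free = float(np.mean([lp.free_bp for lp in model.loops]))
    r0 = mean_free * rise_nm_per_bp / 1000.0 / 2.0

    def noisy(center: float) -> np.ndarray:
        if noise_cv == 0:
            return np.full(n, center)
        vals = center * (1.0 + noise_cv * rng.standard_normal(n))
        return np.abs(vals)  # physical measurements are positive

    records = pd.DataFrame(
        {
            "nucleus_diameter_um": noisy(nucleus_diameter_um),
            "nm_diameter_um": noisy(nm_diameter_um),
            "halo_radius_um": noisy(r0),
        }
    )
    return HaloMeasurementSet(label=label, records=records)


# -- fixture export/import ----------------------------------------------------

def export_fixture(model: NucleoidModel, amplicons, path_prefix) -> dict:
    """Write the model as FASTA + BED + YAML; re-importable exactly.

    * ``<prefix>_loops.fasta`` — one random-sequence record per loop
      (deterministic in the model seed), length = loop size in bp;
    * ``<prefix>_features.bed`` — BED6 intervals (chrom = loop_id) for
      both MAR footprints and every amplicon;
    * ``<prefix>_model.yaml`` — authoritative parameters and loop table.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.parent / f"{prefix.name}_loops.fasta"
    bed = prefix.parent / f"{prefix.name}_features.bed"
    meta = prefix.parent / f"{prefix.name}_model.yaml"

    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    records = []
    for loop in model.loops:
        length = int(round(loop.total_bp))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        records.append(SeqRecord(Seq(seq), id=loop.loop_id, description=""))
    try:
        seqio_write(records, str(fasta), "fasta")
    except OSError as err:
        raise OSError(f"cannot write FASTA {fasta}: {err}") from err

    lines = []
    for loop in model.loops:
        total = int(round(loop.total_bp))
        left = int(round(loop.left_footprint_bp))
        right = int(round(loop.right_footprint_bp))
        if left > 0:
            lines.append(f"{loop.loop_id}\t0\t{left}\t{loop.loop_id}_MAR_left\t0\t.")
        if right > 0:
            lines.append(
                f"{loop.loop_id}\t{total - right}\t{total}\t{loop.loop_id}_MAR_right\t0\t."
            )
    for amp in amplicons:
        start = int(round(amp.start_bp))
        end = int(round(amp.end_bp))
        lines.append(f"{amp.loop_id}\t{start}\t{end}\t{amp.name}\t0\t.")
    bed.write_text("\n".join(lines) + ("\n" if lines else ""))

    payload = {
        "profile": {"k0": model.profile.k0, "alpha": model.profile.alpha},
        "seed": model.seed,
        "absorbed_bp": model.absorbed_bp,
        "absorbed_loop_ids": sorted(model.absorbed_loop_ids),
        "loops": [
            {
                "loop_id": lp.loop_id,
                "total_bp": lp.total_bp,
                "left_footprint_bp": lp.left_footprint_bp,
                "right_footprint_bp": lp.right_footprint_bp,
            }
            for lp in model.loops
        ],
        "amplicons": [
            {
                "name": a.name,
                "loop_id": a.loop_id,
                "start_bp": a.start_bp,
                "length_bp": a.length_bp,
                "chromosome_label": a.chromosome_label,
                "expressed": a.expressed,
            }
            for a in amplicons
        ],
    }
    meta.write_text(yaml.safe_dump(payload, sort_keys=False))
    return {"fasta": fasta, "bed": bed, "yaml": meta}


def import_fixture(path_prefix) -> tuple:
    """Inverse of :func:`export_fixture`: (model, amplicons) from YAML."""
    prefix = Path(path_prefix)
    meta = prefix.parent / f"{prefix.name}_model.yaml"
    if not meta.exists():
        raise FileNotFoundError(f"fixture metadata not found: {meta}")
    payload = yaml.safe_load(meta.read_text())
    loops = [
        Loop(
            loop_id=d["loop_id"],
            total_bp=d["total_bp"],
            mars=(
                MatrixAttachmentRegion(d["loop_id"], "left", d["left_footprint_bp"]),
                MatrixAttachmentRegion(d["loop_id"], "right", d["right_footprint_bp"]),
            ),
        )
        for d in payload["loops"]
    ]
    model = NucleoidModel(
        loops=loops,
        profile=AccessibilityProfile(**payload["profile"]),
        seed=payload["seed"],
        absorbed_bp=payload.get("absorbed_bp", 0.0),
        absorbed_loop_ids=set(payload.get("absorbed_loop_ids", [])),
    )
    amplicons = [Amplicon(**d) for d in payload.get("amplicons", [])]
    return model, amplicons
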