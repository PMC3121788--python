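"""Core data model for nucleoid loop ensembles.

A *nucleoid* is a lysed, histone-depleted nucleus: the proteinaceous
nuclear matrix (NM) plus naked, supercoiled DNA loops that stay anchored
to it through matrix attachment regions (MARs).  The classes here
describe that geometry for simulation purposes:

* every loop is anchored at both ends (a loop by definition returns to
  the NM), with one MAR footprint per anchor;
* DNA inside a MAR footprint is treated as embedded within the NM and is
  never cleaved by DNase I;
* accessibility of free loop DNA to the nuclease rises from the loop
  base to the loop apex, collapsing steric hindrance by the NM and the
  base-ward gradient of supercoiling into a single monotone profile.

Lengths are expressed in base pairs and stored as floats: loop sizes are
drawn as whole base pairs, but MAR footprints and their growth under the
anchor-extension aging model are continuous quantities so that DNA-mass
bookkeeping is exact.  Coordinates are 0-based and half-open; the loop
arc fraction ``u`` runs from 0 (left anchor) to 1 (right anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError

__all__ = [
    "MatrixAttachmentRegion",
    "Loop",
    "AccessibilityProfile",
    "NucleoidModel",
    "Amplicon",
    "SimulationConfig",
]


@dataclass(frozen=True)
class MatrixAttachmentRegion:
    """One NM anchor of a loop: ``footprint_bp`` of DNA bound to the matrix."""

    loop_id: str
    side: str  # "left" or "right"
    footprint_bp: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidParameterError(f"MAR side must be 'left'/'right', got {self.side!r}")
        if self.footprint_bp < 0:
            raise InvalidParameterError(f"footprint_bp must be >= 0, got {self.footprint_bp}")


@dataclass(frozen=True)
class Loop:
    """A supercoiled DNA loop anchored to the NM at both ends.

    ``total_bp`` includes the two MAR footprints; ``free_bp`` is the
    nuclease-exposed span between them.  A loop with ``free_bp == 0`` is
    fully embedded in the NM.
    """

    loop_id: str
    total_bp: float
    mars: tuple[MatrixAttachmentRegion, MatrixAttachmentRegion]

    def __post_init__(self) -> None:
        if self.total_bp <= 0:
            raise InvalidParameterError(f"total_bp must be > 0, got {self.total_bp}")
        left, right = self.mars
        if left.side != "left" or right.side != "right":
            raise InvalidParameterError("mars must be ordered (left, right)")
        if left.footprint_bp + right.footprint_bp > self.total_bp + 1e-9:
            raise InvalidParameterError(
                f"loop {self.loop_id}: MAR footprints "
                f"({left.footprint_bp} + {right.footprint_bp}) exceed total_bp {self.total_bp}"
            )

    @property
    def left_footprint_bp(self) -> float:
        return self.mars[0].footprint_bp

    @property
    def right_footprint_bp(self) -> float:
        return self.mars[1].footprint_bp

    @property
    def embedded_bp(self) -> float:
        return self.left_footprint_bp + self.right_footprint_bp

    @property
    def free_bp(self) -> float:
        return max(self.total_bp - self.embedded_bp, 0.0)

    @property
    def is_fully_embedded(self) -> bool:
        return self.free_bp <= 1e-9

    def with_footprints(self, left_bp: float, right_bp: float) -> "Loop":
        return Loop(
            loop_id=self.loop_id,
            total_bp=self.total_bp,
            mars=(
                MatrixAttachmentRegion(self.loop_id, "left", left_bp),
                MatrixAttachmentRegion(self.loop_id, "right", right_bp),
            ),
        )


@dataclass(frozen=True)
class AccessibilityProfile:
    """DNase-I accessibility gradient along a loop.

    The per-bp cleavage hazard at arc fraction ``u`` is
    ``k0 * a(d)`` with ``d = min(u, 1 - u)`` and ``a(d) = (d / 0.5)**alpha``:
    0 at the anchors, 1 at the loop apex.  ``alpha`` controls how steeply
    protection decays away from the NM (``alpha = 0`` gives a uniform
    hazard); it jointly represents steric hindrance by the NM and the
    higher supercoiling of base-proximal DNA.  Hazard inside MAR
    footprints is exactly 0 (the non-digestible embedded fraction).

    Units: ``k0`` in cuts · bp⁻¹ · min⁻¹ at full accessibility.
    """

    k0: float
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise InvalidParameterError(f"k0 must be >= 0, got {self.k0}")
        if self.alpha < 0:
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha}")

    def accessibility(self, d):
        """a(d) for arc distance d in [0, 0.5]."""
        import numpy as np

        d = np.asarray(d, dtype=float)
        if self.alpha == 0:
            return np.ones_like(d)
        return (2.0 * d) ** self.alpha


@dataclass
class NucleoidModel:
    """An ensemble of NM-anchored loops plus the accessibility profile.

    ``absorbed_bp`` accounts for DNA of loops that were entirely merged
    into the NM by the anchor-extension aging model; it stays part of the
    total (and embedded) DNA mass so that evolution conserves mass.
    """

    loops: list[Loop]
    profile: AccessibilityProfile
    seed: int = 0
    absorbed_bp: float = 0.0
    absorbed_loop_ids: set[str] = field(default_factory=set)

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    @property
    def total_bp(self) -> float:
        return sum(lp.total_bp for lp in self.loops) + self.absorbed_bp

    @property
    def embedded_bp(self) -> float:
        return sum(lp.embedded_bp for lp in self.loops) + self.absorbed_bp

    @property
    def embedded_fraction(self) -> float:
        total = self.total_bp
        return self.embedded_bp / total if total > 0 else 0.0

    def loop_by_id(self, loop_id: str) -> Loop:
        for lp in self.loops:
            if lp.loop_id == loop_id:
                return lp
        raise KeyError(f"no loop with id {loop_id!r}")

    def to_frame(self):
        """Loop table as a DataFrame (one row per loop)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "loop_id": [lp.loop_id for lp in self.loops],
                "total_bp": [lp.total_bp for lp in self.loops],
                "left_footprint_bp": [lp.left_footprint_bp for lp in self.loops],
                "right_footprint_bp": [lp.right_footprint_bp for lp in self.loops],
                "free_bp": [lp.free_bp for lp in self.loops],
            }
        )


@dataclass(frozen=True)
class Amplicon:
    """A PCR target interval at a fixed position within one loop.

    ``expressed`` is a boolean annotation only (no expression modeling).
    """

    name: str
    loop_id: str
    start_bp: float
    length_bp: float
    chromosome_label: str = ""
    expressed: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise InvalidParameterError(f"amplicon {self.name}: length_bp must be > 0")
        if self.start_bp < 0:
            raise InvalidParameterError(f"amplicon {self.name}: start_bp must be >= 0")

    @property
    def end_bp(self) -> float:
        return self.start_bp + self.length_bp


@dataclass(frozen=True)
class SimulationConfig:
    """Digestion / detection sampling design.

    ``detection_threshold`` is the minimum fraction of nucleoids that
    must retain an intact, NM-attached copy of an amplicon for a
    PCR-positive call; it stands in for the gel-image scoring
    sensitivity, which is not quantifiable from first principles.
    ``dnase_u_per_ml`` is carried as assay metadata only.
    """

    timepoints_min: tuple = (0.0, 5.0, 15.0, 30.0, 60.0)
    n_nucleoids: int = 10_000
    n_replicates: int = 4
    detection_threshold: float = 1e-3
    dnase_u_per_ml: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints_min)
        object.__setattr__(self, "timepoints_min", tp)
        if len(tp) < 1 or tp[0] != 0.0:
            raise InvalidParameterError("timepoints_min must start at 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise InvalidParameterError("timepoints_min must be strictly increasing")
        if any(t < 0 for t in tp):
            raise InvalidParameterError("timepoints_min must be non-negative")
        if not (0.0 < self.detection_threshold <= 1.0):
            raise InvalidParameterError("detection_threshold must be in (0, 1]")
        if self.n_nucleoids < 1:
            raise InvalidParameterError("n_nucleoids must be >= 1")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
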