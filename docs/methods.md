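# Methods

## The system being modeled

A nucleoid is what remains of a nucleus after high-salt lysis in
non-ionic detergent: the proteinaceous nuclear matrix (NM) plus naked,
topologically constrained DNA loops anchored to it through matrix
attachment regions (MARs).  Limited DNase-I digestion removes loop DNA
outside-in — distal (apex) sequences first, anchor-proximal sequences
later, MAR-embedded DNA essentially never — so the time at which a
given sequence stops being PCR-amplifiable from NM-bound template
reports its distance from the NM.  The package models this assay,
analyzes its outputs, and simulates how the loop organization changes
with age.

## Digestion model

Each loop has total length `L` bp with MAR footprints `f_L`, `f_R` at
its two anchors (a loop by definition returns to the NM, so both-end
anchoring is assumed; the loop apex is the point farthest from either
anchor).  Positions are arc fractions `u ∈ [0, 1]`; the distance
coordinate is `d(u) = min(u, 1−u)`.

Cuts form a non-homogeneous Poisson process with per-bp hazard

    h(u) = k0 · a(d(u)),    a(d) = (d / 0.5)^α,

zero inside MAR footprints.  `a` collapses two protection factors the
assay cannot separate — steric hindrance by the NM body and the higher
supercoiling of base-proximal DNA — into one monotone gradient: 0 at
the anchors, 1 at the apex.  A cut fragment stays NM-attached iff it
still contains footprint DNA; with anchors at both ends these are
exactly the outermost two fragments.

The per-position survival-attached probability has a closed integral
form by inclusion–exclusion ("no cut between u and either anchor"):

    S(u, t) = e^(−H(b_L, u)) + e^(−H(u, b_R)) − e^(−H(b_L, b_R)),

where `H(x, y) = t·k0·L·(A(y) − A(x))` is the cumulative hazard and
`A(u) = ∫ a(d(s)) ds` has an elementary antiderivative.  The expected
attached mass fraction integrates `S` over the free span (scipy `quad`,
relative tolerance 1e−9) — this is the analytic oracle for the
Monte-Carlo sampler.  In the uniform-hazard limit (α → 0, no
footprints) it reduces to `(2/θ)(1 − e^(−θ)) − e^(−θ)` with
`θ = t·k0·L`, which the tests verify both against quadrature and
against an independent enumeration over Poisson cut configurations.

The sampler draws, per nucleoid and loop, `N ~ Poisson(H_total)` cuts
with exact inverse-CDF positions from the accessibility density and
i.i.d. uniform cut times on `[0, t_max]`; thinning by time yields every
earlier time point from the same draw, making each simulated time
course monotone non-increasing by construction and never below the
embedded floor.

## Detection and zone calling

An amplicon survives at time t iff its interval is uncut *and* lies on
an attached fragment — equivalently, no cut between the left anchor and
its right edge, or none between its left edge and the right anchor.
Per replicate (independent seed substream) the detection call is
`survival fraction ≥ detection_threshold` over the replicate's own
nucleoid sample.  The threshold (default 1e−3) stands in for the
gel-image scoring sensitivity, which has no first-principles value; it
is an explicit parameter.

Replicates collapse to `+` (all positive), `−` (none), `±` (some).  The
position call is the innermost (longest-digestion) zone whose symbol is
positive; `±` counts as positive by default (a strict mode is
available) and sets the call's `ambiguous` flag when it determines the
call.  Outside-in digestion makes admissible patterns monotone —
positives then negatives — so a positive inward of a negative, or a
pattern with no positive, is a QC failure, reported rather than
repaired.  Distance ranks are fixed integers (E = 1, VC = 2, P = 3,
D = 4) used only for shift statistics, never mapped to µm.

## Kinetics analysis

Time courses are analyzed model-free (no exponential fits — only
piecewise slopes are reported in this assay): raw local slopes
`Δpct/Δt`, rounded half-away-from-zero to 1 decimal, the terminal
plateau, and a zone scheme binding ordered labels to the non-zero time
points.  The bundled newborn (P0) course carries two reported slopes
that are not the finite differences of its own percentages
(−2.2 and −3.4 reported vs −0.5 and −0.3 recomputed over 15–30 and
30–60 min); `compare_with_published` flags them instead of
special-casing.  Reported SDs are carried for display only; zone
boundaries sit at the sampled time points.

## Halo quantitation

A loop of `k` kbp unwinds into a halo of radius
`R = k·1000·rise / 1000 / 2` µm (out-and-back B-DNA path), i.e.
`k = 2R/0.34 ≈ 5.88·R` at the canonical 0.34 nm/bp rise.  The
published calibration behind the reference loop sizes is not printed
with them, so the rise is an explicit parameter; the default gives the
familiar 42 kbp ↔ 7.14 µm correspondence.  Group comparisons use the
pooled-variance Student's *t* (the convention for equal-n morphometric
groups; Welch by flag), with the degenerate identical-constant-samples
case defined as t = 0, p = 1.  NM resilience is the ratio of mean NM
diameter to mean nuclear diameter, "resilient" iff > 1.

## Aging operators

* **Model A (MAR substitution):** each loop independently re-anchors
  with probability `p_sub`; its size is re-drawn from the configured
  lognormal and its per-side footprint fractions are preserved.  Gene
  amplicons on re-anchored loops are re-placed uniformly within the new
  free span: the new anchors land at random positions relative to the
  fixed genomic offset of the gene, so the in-loop position is
  effectively randomized.
* **Model B (MAR extension):** each footprint grows by a draw from the
  extension distribution (default: deterministic 10% of the loop's free
  DNA per anchor, i.e. 20% of free DNA absorbed overall), clipped so
  free DNA never goes negative.  A loop whose free span vanishes is
  merged into the NM: it leaves the loop list but its mass is retained
  in the model's `absorbed_bp`, so total DNA is conserved exactly and
  the embedded fraction obeys `e' = e + φ(1 − e)` for absorbed free
  fraction φ.  Surviving-loop sizes are untouched.

Model B's qualitative claim that genes end up distal to the NM has no
specified geometric mechanism at the single-loop level; in this
geometry anchor extension leaves a free amplicon's hazard essentially
unchanged (its arc coordinate is fixed) and can only move it to E by
absorption.  The zone-rank shift after model B is therefore tested
qualitatively only (median shift ≥ 0); the positional aging signature
itself is carried by the bundled observed table, where 9/9 genes move
away from the NM between P0 and P540.

## Synthetic-data generator: defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| loop-size distribution | lognormal, mean 42 kbp, CV 0.1 | matches the reference newborn-neuron loop size 42 ± 4.02 kbp |
| embedded fraction | 0.02 | the ~2% DNase-resistant DNA buried in the NM |
| accessibility exponent α | 2 | smooth protection gradient; α is the main unknown and is configurable |
| base hazard k0 | 2e−4 cuts·bp⁻¹·min⁻¹ | produces time courses on the observed scale over 0–60 min at the assay's 0.92 U/ml DNase (carried as metadata) |
| time points | 0, 5, 15, 30, 60 min | the assay's sampling design |
| replicates | 4 | the assay's n ≥ 4 |
| nucleoids per replicate | 10,000 | enough that a 1e−3 detection threshold is ~10 template copies |
| detection threshold | 1e−3 | explicit stand-in for gel scoring sensitivity |
| halo noise | multiplicative Gaussian CV | measurement scatter only |

The generator emulates anchored-loop geometry, the accessibility
gradient, the embedded fraction, replicate PCR detection and noisy halo
morphometry.  It does **not** emulate chromatin (nucleoids are
histone-free by construction), sequence-specific MAR biology,
inter-loop spatial structure, gel densitometry, or intercalator-driven
unwinding dynamics.  Passing recovery tests therefore show the
analysis pipeline is consistent and well-calibrated under the model's
assumptions, not that those assumptions hold in any particular real
nucleus.

## Planted-probe recovery

`run_recovery_experiment` plants nine probe amplicons — two per outer
zone band, three embedded-band — on distinct loops of a 1000-loop
ensemble.  Probe positions are solved by bisection on the analytic
amplicon survival so that survival at the probe's own zone time point
is 0.01 (an expected ~100 surviving templates of 10,000: solidly
detectable) while the near-exponential decay in time leaves < 2e−4 by
the next time point (expected ≤ 2 copies: solidly negative); the
designer verifies these margins and refuses designs that violate them.
Embedded-band probes sit just outside the footprint with survival 0.05
at the last time point.  The experiment then simulates detection, calls
zones, reports accuracy and the zone-confusion table, ages the ensemble
under model B, and reports mass conservation, embedded-fraction change,
loop-size drift and the median zone-rank shift.  All stage seeds derive
from one master seed; identical seeds give byte-identical report files.

## Numerical choices and degenerate inputs

* Lengths are floats (bp); loop sizes are drawn as whole bp but
  footprints and extensions are continuous so the model-B conservation
  identities hold to double precision.
* Rounding of reported slopes: half-away-from-zero via `decimal`, not
  banker's rounding.
* α = 0 is allowed and means a uniform hazard (the closed-form limit).
* detection_threshold = 1 is allowed; it makes every free probe
  undetectable beyond t = 0 and exercises the all-calls-fail-QC path
  (nonzero CLI exit).
* k0 = 0 or t = 0 short-circuit to fully attached / all-positive.
* Digestion beyond the last configured time point is not modeled
  (slopes are near zero there).
* Fixture export writes FASTA (random sequence, deterministic in the
  model seed), BED6 intervals and a YAML parameter file; the YAML is
  authoritative for re-import.

## Problem sizes

Default analyses run at 10,000 nucleoids per replicate for detection
(9 probe loops only are simulated), 200 nucleoids for whole-ensemble
time courses, 1000-loop ensembles for distribution-level checks and
3000–10,000 nucleoids for the Monte-Carlo/analytic cross-checks —
sizes chosen so Monte-Carlo error is well below the effects being
measured while a full validation run completes in well under a minute
per stage.

## Known limitations

* The accessibility profile is a single power law; real protection
  likely combines distinct steric and topological terms with unknown
  shapes.  Only the monotone ordering is essential to the zone logic.
* The halo→kbp conversion assumes fully extended B-DNA; crowding and
  incomplete unwinding bias real halos low.
* Zone calls quantize a continuous position into four bins bounded by
  the sampling times; probes near a survival boundary can
  legitimately straddle two zones across replicates (the ± calls).
* Model A's amplicon re-placement and model B's gene-displacement
  geometry are the package's own constructions where the underlying
  biology is unspecified; both are flagged above.
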