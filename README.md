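# nmloops

Quantifying the stability of the **nuclear higher-order structure
(NHOS)** — the genome-wide pattern of supercoiled DNA loops anchored to
the nuclear matrix (NM) through matrix attachment regions (MARs) — from
the standard nucleoid assays used on post-mitotic cells such as cortical
neurons.

The package is for researchers who work with nucleoid preparations
(lysed, histone-free nuclei) and need reproducible, scriptable versions
of the downstream quantitation:

* **digestion kinetics** — limited DNase-I digestion time courses
  (% NM-attached DNA vs time), local slopes
  `S_i = (pct_{i+1} − pct_i)/(t_{i+1} − t_i)`, plateaus, and the
  topological-zone scheme (D = distal, P = proximal, VC = very close,
  E = embedded, bound to successive digestion time points);
* **positional mapping** — calling each gene target's zone as the
  innermost zone at which it is still PCR-amplifiable from NM-bound
  template, with bench `+ / ± / −` replicate semantics and age-to-age
  shift statistics;
* **DNA-halo quantitation** — loop-size estimation
  `kbp = 2·R(µm)/rise(nm/bp)` from maximum halo radii, per-group
  mean ± SD summaries, pooled-variance Student's *t*-tests and the
  NM-resilience check (NM diameter > nuclear diameter);
* **a mechanistic simulator** — a Monte-Carlo model of NM-anchored
  loops under limited digestion.  Each loop is cut by a
  non-homogeneous Poisson process with per-bp hazard `k0·(2d)^α`,
  where `d = min(u, 1−u)` is the arc distance from the nearest anchor:
  steric hindrance by the NM and the base-ward supercoiling gradient
  collapsed into one monotone accessibility profile.  MAR footprints
  have hazard 0 (the ~2% non-digestible embedded fraction).  A closed
  integral form of the per-position survival probability provides an
  exact analytic oracle for the sampler;
* **two aging models** — MAR *substitution* (A: loops re-drawn, genes
  randomized) and MAR *extension* (B: anchors absorb adjacent free
  DNA, embedded fraction rises, loop count falls, sizes untouched,
  mass conserved exactly).

## Worked example

```bash
python examples/digestion_kinetics.py
```

prints, from the bundled neuron reference data:

```
Local digestion slopes S (percentage points / min):
     P0: (-8.8, -3.1, -0.5, -0.3)  plateau 8.8%
     P7: (-10.2, -2.5, -0.3, -0.1)  plateau 17.4%
    P80: (-6.7, -2.9, -0.8, -0.3)  plateau 17.4%
   P540: (-4.7, -2.0, -0.7, -0.7)  plateau 26.4%
```

Each tuple is the loss rate of NM-attached DNA over the 0–5, 5–15,
15–30 and 30–60 min digestion intervals; the plateau is the
non-digestible residue.  Old (P540) neurons digest more slowly and
plateau far higher than newborn (P0) neurons — more of their DNA sits
close to or inside the NM, the signature of an aging-stabilized NHOS.
The script also flags the two P0 intervals whose reported slopes are
not the finite differences of the reported percentages.

Other examples: `positional_mapping.py` (36 zone calls and the
newborn→old shift: 9 genes move away from the NM, 0 toward),
`simulate_digestion.py` (Monte Carlo vs analytic expectation),
`halo_loop_size.py` (42 kbp loops ↔ 7.14 µm halos, group *t*-tests),
`aging_models.py` (model A vs B head to head).

A thin CLI wraps the same stages:

```bash
nmloops kinetics --in timecourses.tsv --out slopes.tsv
nmloops map --scores scores.tsv --scheme scheme.tsv --out calls.tsv
nmloops halo --in measures.csv --alpha 0.01 --out summary.tsv
nmloops simulate --config run.yaml --seed 1 --out outdir
nmloops recover --config run.yaml --seed 1 --out outdir
```

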