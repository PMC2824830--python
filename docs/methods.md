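# Methods

## Problem and scope

B-DNA double helices in crystals pack against one another in crossover
arrangements.  Because the helix is chiral, the two handednesses of a
crossover are not equivalent: right-handed crossings (positive crossing
angle) permit a "knob into hole" self-fitting in which the sugar-phosphate
backbone of one duplex lies inside a groove of the other, while left-handed
crossings only allow groove-to-groove apposition.  The pipeline measures, for
any crystal structure containing nucleic-acid duplexes:

1. the symmetry-expanded packing neighbourhood,
2. the best linear helical axis of each duplex,
3. the signed acute crossing angle α of each juxtaposed pair,
4. the interaction mode (major/minor groove-backbone, major↔major,
   minor↔minor, major↔minor), the cytosine/guanine amino-group anchors of a
   penetrating phosphate, and bridging cations.

Free-energy estimation, supercoiling simulation, and writhe/linking-number
computation are out of scope.

## Sign convention for α

Axis directions u, v are folded to u·v ≥ 0 (the acute angle is reported);
with c the vector between the closest points on the two axes,
α = sign((u×v)·c)·arccos(u·v) ∈ (−90°, +90°].  Exactly-perpendicular
crossings are reported as +90 (fold-boundary tie).  The orientation of the
(+) sign is pinned two independent ways in the tests:

* **Gauss-linking construction** — an explicit right-handed interwound
  superhelix (the plectoneme geometry of underwound DNA) must yield α < 0,
  its mirror α > 0;
* **groove-tracking construction** — a duplex whose backbone tracks the
  major groove of a partner (only possible with right-handed crossing
  geometry) must yield α > 0.

Both agree with the triple-product formula with no extra calibration factor.
Duplex axes are unoriented, so the folded convention makes α well-defined:
it is exchange-symmetric, invariant under proper rigid motions (tested at
1e-9), and anti-symmetric under reflection (a pseudoscalar).

## Helical axes

The axis is the total-least-squares line (first principal component) through
the base-pair origins, defined as C1′-atom midpoints; the direction is
signed along strand I 5′→3′.  The fit rmsd is reported and an rmsd > 2.0 Å
sets a curvature flag: a single straight axis is then meaningless, and for
duplexes longer than 12 pairs the crossover search re-fits the axis in a
12-pair window centred on the closest-approach point (iterated twice).  The
rmsd of 147-bp nucleosomal DNA is far above the flag; short crystal duplexes
(10–12 bp) sit well below it.  Exactly collinear origins give rmsd = 0
identically (the direction vector is renormalised so the residual collapses
exactly).

## Base pairs and reference frames

Watson-Crick pairs are called geometrically: purine N1 – pyrimidine N3
≤ 3.5 Å, base-plane normals within 65°, C1′–C1′ within [9.0, 11.5] Å;
assignment is greedy one-to-one on the N1–N3 distance, then restricted to
the longest antiparallel register (strand II residue numbers strictly
decreasing along strand I) — this discards the occasional diagonal mispair
that passes the raw distance windows in noisy coordinates.  Modified bases
(5-methylcytosine, inosine, 2-aminopurine-class residues) pair through their
parent-base atoms.

The pair frame follows the standard reference-frame convention: origin at
the C1′ midpoint, **x** toward the major groove, **y** along C1′–C1′ toward
strand I, **z** = x×y completing the right-handed triad along the strand-I
5′→3′ progression.  Operationally y and the base-plane normal are measured,
and the normal's sign is chosen so that x points at the major-groove edge
atoms (N7/O6/N6/C5 of purines, C5/N4/O4 of pyrimidines); with correct WC
geometry this automatically orients z along the helix.

## Groove sectors and interaction modes

A point is assigned to a groove of a duplex through the frame of the nearest
base pair by axial projection: the in-plane angle θ from +x gives *major*
(|θ| ≤ 60°), *minor* (|θ| ≥ 120°) or *backbone side* (the flanks); the three
sectors partition the circle.  Because the groove direction rotates with the
helix (~36° per step), the frame azimuth is unwound by the locally estimated
twist rate times the axial offset of the query point — without this
correction a detection gap of a single base pair next to the contact would
rotate the reference by a full twist step.

A phosphorus atom of one duplex *penetrates* the partner when its sector
there is major (or minor) with radial distance ≤ 10.5 Å from the fitted
axis.  The B-DNA phosphate radius is ≈ 9–10 Å, so a partner phosphate inside
this radius is genuinely inserted; the value is configurable and the
classification on fixtures is insensitive to ±0.5 Å.  Any major-penetration
→ *Major-groove/backbone*; else minor-penetration → *Minor-groove/backbone*;
otherwise the grooves facing the partner across the closest-approach vector
decide the groove-groove mode, and an unresolvable facing (backbone side)
yields *Unclassified*.

Anchors: for each penetrating phosphate, cytosine N4 donors (major-groove
modes) or guanine N2 donors (minor-groove mode) of the penetrated duplex are
measured to the phosphate oxygens.  ≤ 3.4 Å → hydrogen-bond anchor;
[3.5, 4.5] Å → proximal anchor; the (3.4, 3.5) gap is deliberate so the two
categories are disjoint.  All criteria are heavy-atom distances (hydrogens
are ignored throughout).  A cation bridges a crossover when it contacts ≥1
DNA atom of each duplex within 4.0 Å — looser than inner-sphere
coordination (≈2.1–2.6 Å) because waters are frequently unmodelled in older
depositions; monovalent ions are reported but flagged non-divalent.
Hexammine-cobalt sites are treated as a single cation at the metal.

## Crystal symmetry

Space-group operators come from the coordinate file when present (mmCIF
categories) and otherwise from an internal table of xyz-triplet general
positions covering the groups that occur in B-DNA packing work (triclinic
through hexagonal, rhombohedral groups in the hexagonal setting).  The table
is verified by a group-closure test: composing any two operators must land
back in the set modulo lattice translations, which catches wrong screw or
centring translations.  Expansion combines every operator with integer
lattice shifts (bound: ⌈(radius + model extent)/cell height⌉ + 1 per axis,
validated against brute-force enumeration) and keeps copies with any
nucleic-acid atom within the contact radius (default 25 Å — juxtaposed
duplex separations of interest are ≤ ~22 Å).  Copies are exact isometries
(rigidity tested at 1e-6 Å) and carry operator + shift provenance into all
reports.  Crossovers are anchored to the asymmetric unit (at least one
duplex from the identity copy) and symmetry-equivalent crossovers are
collapsed to one representative by a (angle, distance, sequences) key.

## Synthetic constructs (what a green test establishes)

The fixture builder is a coarse fiber model with exact ground truth, not a
refinement-grade DNA model:

* **Pair geometry** — in-plane base atoms come from the chemical component
  dictionary's ideal nucleotides, rigid-fitted (2D, chirality-canonicalised)
  onto standard base-pair reference-frame anchor coordinates; the resulting
  WC hydrogen bonds are 2.86–3.10 Å and C1′–C1′ is 10.8 Å.
* **Stacking** — pairs are planar, twisted 36.0°/step and risen 3.38 Å/step
  about the axis through the C1′ midpoints; no propeller, slide or roll, so
  the fitted axis and all pair origins are exact by construction.
* **Backbone** — sugars are rigid-fitted per residue; the glycosidic
  torsion and the analytic 5′-phosphate site (radius 8.44 Å) were solved
  once, jointly, for chain connectivity (O5′–P, O3′–P ≈ 1.7–2.0 Å) given
  the CCD sugar conformer.  With that conformer's pucker the canonical
  *anti* torsion cannot close the chain, so the builder trades torsional
  purity for a connected, regularly placed backbone.  The pipeline consumes
  base geometry and phosphate positions, never torsion profiles.
* **Crossover posing** — duplex B is rolled about its own axis so the
  requested face (backbone phosphates or a groove floor) points at duplex A,
  then tilted by α about the inter-axial normal and translated to the
  requested separation; the designed α and distance are recovered to 1e-6 by
  the full pipeline.  Mode templates are sampled in their geometrically
  realisable separation ranges: backbone insertion requires ≈ 14–18.5 Å
  between axes (phosphate radius 8.4 Å + penetration radius 10.5 Å), groove
  apposition ≈ 18.5–25 Å; outside these ranges the same atomic criteria
  correctly report a different (or no) interpenetration, which is physics,
  not error.

A green synthetic suite therefore establishes the correctness of the
geometry (angles, chirality, sectors, windows, symmetry) — it does not
establish sequence-dependent fine structure, crystallographic disorder
handling, or solvent-mediated contacts, which only the deposited-structure
regression can probe.

Noise is isotropic per-atom Gaussian, seeded; at σ = 0.3 Å the interaction
mode is recovered in ≥95% of constructs (the residual failures are eroded
base-pair detection near the WC thresholds, not misclassification).

## Defaults

| parameter | default | meaning |
|---|---|---|
| contact_radius | 25 Å | symmetry-expansion cutoff |
| max_interaxial | 22 Å | crossover definition |
| min_overlap | 3.4 Å | closest points interior to both segments by one rise |
| penetration_radius | 10.5 Å | phosphate "inserted" when closer to partner axis |
| hbond_cutoff | 3.4 Å | anchor hydrogen bond (heavy atoms) |
| proximal_window | 3.5–4.5 Å | near-anchor window |
| bridge_cutoff | 4.0 Å | ion–DNA contact |
| curvature_rmsd | 2.0 Å | straight-axis validity |
| window_size | 12 pairs | contact-local axis for bent DNA |

All live in `RunConfig`, serialise to a flat key=value file, and are logged
per run.

## Known limitations

* The linear axis is not a curvilinear helical axis; for strongly bent
  duplexes the windowed fit approximates the contact-local axis and results
  are flagged low-confidence via the curvature flag.
* Drug atoms (minor-groove binders, polyamides) are carried but excluded
  from DNA-DNA contact classification; drug-mediated packing is not
  modelled.
* Occupancy-based alt-loc selection keeps a single conformer; correlated
  disorder is ignored.
* The deposited-structure regression requires network-obtained coordinate
  files; it cannot run in a fully offline environment and reports exactly
  which accessions are missing.
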