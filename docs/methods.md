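# Methods

This note records the model as implemented, the defaults and why they hold,
what the synthetic reference emulates, and the choices made where the
design was genuinely open.

## Mapping model

Only closed-ring monosaccharides (pyranoses and furanoses) are modeled;
ring-open forms are a negligible solution fraction and are rejected with a
"ring not found" error. Anomers of *free* monosaccharides are not
distinguished — their mapped geometries are nearly identical — but α- and
β-glycosidic bonds in oligomers are distinct term types with separately
fitted lengths, because the relative ring placement differs measurably.

Fragment assignment operationalizes the three mapping rules as a search
over contiguous chunkings of the ring traversal (anomeric carbon first,
increasing ring-carbon numbering, ring oxygen last, exocyclic subtrees
inline). A valid chunk has 2–4 heavy atoms (5 when it absorbs a declared
keep-together group such as the sialic-acid carboxylate), is a connected
subgraph, and the final ring chunk must contain the ring ether. Among valid
partitions the score prefers more 4-atom chunks (rule 1), then fewer 2-atom
chunks, then fewer chunks, ties broken toward front-loaded sizes. This
reproduces the shipped decompositions for all eleven residue templates,
which in turn pass the mismatch rule (|heavy − implied| ≤ heavy/10 with
regular/small/tiny beads counting 4/3/2 and the virtual site counting as a
tiny bead).

"Counterclockwise" traversal is encoded as increasing ring-carbon
numbering: ring drawings are orientation-dependent, atom numbering is not.

Bead-type labels: the running rules fix SP1r (hemiacetal and 1-1…1-4
glycosidic fragments), SN6r (1-5/1-6), TC4 (virtual site) and the standard
P2 carboxylic acid bead for the acid-grouped sialic fragment. All other
labels (diol SP4r, ring-ether variants, acetamide SP2a, …) are this
package's own choices recorded — and flagged `unverified` — in
`src/sugarcg/data/fragments.tsv`, so the figure-reading risk is isolated in
one reviewable file. They do not affect any quantitative result computed
here; they name nonbonded types consumed by an external engine.

At a glycosidic bond the donor residue loses its anomeric hydroxyl oxygen
and the bridging ether oxygen is bookkept with the donor-side residue's
B-bead fragment (the residue with the higher bead numbers), matching the
CHARMM-GUI-style boundary convention the mapping targets. The *bead
retyping* for the link is applied to the donor's A bead — the fragment
whose anomeric hydroxyl became the ether, which is exactly the chemical
rationale for the SN6r assignment.

## Coordinates and mapping

CG coordinates are unweighted centers of geometry over heavy atoms.
Hydrogens are excluded so the mapping is independent of the hydrogen model;
this is configurable in principle but is the package-wide convention.
Molecules are made whole before averaging by sequential minimum-image
chaining in atom-index order (residues are contiguous, so polymers longer
than half the box survive); orthorhombic boxes only.

## Bonded terms and their parameters

* Ring constraints: mean mapped distances × 1.15 (`ScalingPolicy.ring_scale`,
  dimensionless, ≥ 1). The scaling corrects the ~8% SASA underestimate of
  plain COG mapping; its direction is asserted by test (scaled glucose SASA
  3.861 nm² > unscaled 3.622 nm²). Glycosidic bonds and substituent
  anchoring constraints are left unscaled by default.
* Substituent beads (the glucuronic acid D bead, sialic side-chain beads)
  are anchored by constraints to their attachment fragment plus one further
  ring bead — a deterministic two-anchor rule that keeps the residue rigid
  in the spirit of the constraint-polygon model. Floppy substituents would
  need bonds instead; none of the shipped templates requires that.
* Harmonic bonds/angles: `b0`/`θ0` from the (circular) mean, `k = k_B T /
  var`. For restricted bending the same inversion applies because the form
  reduces to harmonic near the minimum (`k(cosθ − cosθ₀)²/2sin²θ ≈
  k(θ−θ₀)²/2`).
* Dihedrals: weighted linear least squares of `−k_B T ln p(φ)` on
  `{1, cos nφ, sin nφ}` for n ≤ 3, weights √p, empty bins floored at 1e-6
  before the log. Histogram bins: 0.002 nm for distances, 2° for angles and
  dihedrals — fixed for reproducibility. Reported as GROMACS proper
  dihedrals `k(1 + cos(nφ − φ_s))`, one line per term (funct 9 when a
  series has several terms).
* The angle set spanning a link is the complete set — every (ring-neighbor,
  linked bead, partner) triple on both sides, up to four angles; the triad
  dihedral uses (linked bead of n, entry bead of n+1, exit bead of n+1,
  linked bead of n+2). Both choices are deterministic and overridable at
  the term-enumeration level.
* Exclusion depth: 1 bonded neighbor by default; 3 when every linkage is
  α-1,6 and the chain has ≥3 residues (dextran-like), for stability with
  the flexible 1-6 link. Virtual sites are excluded against their own ring
  beads.

Parameters are rounded to their serialization precision (1e-5 nm, 0.01°,
0.01 kJ mol⁻¹ rad⁻², 1e-3 kJ mol⁻¹) at assembly time, which makes
write → parse → write byte-stable and topology generation fully
deterministic.

## Synthetic reference trajectories

The generator emulates an atomistic reference at the level the fitting
pipeline consumes: rigid idealized residues (ring atoms on a puckered
circle with 0.15 nm sides, exocyclic atoms radiating outward at 0.145 nm)
whose inter-residue placement is sampled per frame from Boltzmann
distributions with known parameters — bond length Normal(b₀, √(k_BT/k)),
spanning angle likewise, dihedral by inverse-CDF sampling of
exp(−U/k_BT) on a 0.05° grid. Defaults (b₀ = 0.50 nm, k = 7000 kJ mol⁻¹
nm⁻²; θ₀ = 112°, k = 250 kJ mol⁻¹ rad⁻²; single cosine, 6 kJ mol⁻¹)
are typical of mapped sugar dimers. It does **not** emulate intra-ring
flexibility, solvent structure, correlations between neighboring links, or
force-field-specific conformer populations — so passing recovery tests
demonstrates the correctness of the mapping/extraction/fitting machinery,
not the realism of any particular published parameter set. Real parameters
should be fitted from real atomistic references through the same pipeline.

## Analysis defaults

* SASA: deterministic Fibonacci-lattice Shrake–Rupley sampling, 960 points
  per sphere by default; radii per size class from the LJ self-interaction
  minimum (2^(1/6)σ/2 with σ = 0.47/0.41/0.34 nm, i.e. 0.264/0.230/0.191
  nm), probe 0.191 nm; virtual sites carry no surface. The named
  double-cubic-lattice method is replaced by this algorithm-agnostic
  contract; agreement within 1% against a seeded Monte-Carlo surface
  integration is enforced by test. Exactly coincident equal spheres are
  deduplicated so degenerate fixtures count one surface.
* Osmotic protocol: box 5.04156 × 5.04156 × 10.08312 nm, flat-bottom walls
  at ±2.52078 nm from the box center, k = 1000 kJ mol⁻¹ nm⁻². The
  pressure is the two-wall mean force divided by the xy area; the
  kJ mol⁻¹ nm⁻³ → bar factor is computed from scipy's physical constants
  at run time. Errors by block averaging with 5 blocks (standard practice;
  the error model is otherwise unspecified). The ideal-solute fixture
  samples solute z positions from the exact flat-bottom Boltzmann density;
  its reduced pressure approaches c·R·T up to the ~2% Gaussian-tail volume
  of the walls, which is why the van 't Hoff test tolerance is 5%.
* Clusters: minimum-image linker distances below 1.4 nm define edges;
  component sizes via scipy's connected components, frame-averaged.
* Polymer statistics: unweighted Rg over chain beads (virtual sites
  excluded), first-to-last bead end-to-end distance, molecules made whole
  first; Ree raises for chains shorter than two beads.

## Problem sizes used

Tests and the acceptance script run entirely on synthetic references:
monosaccharides use a single rigid frame; oligomer fits use 50–60 frames
for structural/round-trip checks and 5×10⁴ frames for parameter-recovery
checks; direct-sample recovery uses 10⁵ Boltzmann samples; Monte-Carlo
SASA oracles use 4×10⁵ points per sphere; the osmotic fixture uses
2×10⁴ frames of 40 ideal solutes. These sizes give estimator noise well
below the asserted tolerances.

## Known limitations

* The descriptor DSL covers condensed linear/branched glycans with `{n}`
  homopolymer repeats; full IUPAC/GlycoCT nomenclature, database import and
  3D structure perception are out of scope.
* No backward (CG → atomistic) mapping, no mass-weighted mapping, no
  iterative refinement (IBI/force matching), and no MD execution — the
  toolkit generates inputs for and post-processes outputs of an external
  engine.
* Lipid tails, glycolipid linkers and protein coarse-graining are not
  modeled; cluster analysis takes any linker-bead coordinates it is given.
* The eleven shipped templates cover the hexoses, pentoses, deoxy sugars,
  uronic acid, inositol and sialic acid used across the validation set;
  other residues need a template entry (atoms, bonds, fragments) in the
  data files.
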