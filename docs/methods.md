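# Methods

## Problem and model

Given one crystallographic entry and a candidate partition of its chains
(or REMARK 350 symmetry copies) into two binding units, the task is a
binary decision: biological interface vs crystal packing contact.  The
working hypothesis is physical rather than geometric: atoms engaged in a
real binding interface are conformationally ordered, which the deposited
B factors record, whereas lattice contacts recruit ordinary surface with
ordinary mobility.  All scores therefore derive from per-unit
standardized B factors restricted to *interfacial* atoms.

### B-factor normalization

Within one binding unit, b_norm = (B − B̄)/(1.645·δ_B), clipped to
[−1, 1].  The 1.645 constant is the standard normal 95th percentile, so
the unit's two-sided 90% B-factor interval maps onto [−1, 1] and the
tails saturate.  Conventions fixed here: δ_B is the *population* standard
deviation over all retained atoms of the unit (hydrogens and waters are
excluded before statistics, keeping normalization consistent with contact
detection; the paper-scale choice between N and N−1 denominators changes
results by well under 1% at realistic atom counts but is pinned for
reproducibility).  Units with identical B everywhere get b_norm ≡ 0 and
a warning — such depositions carry no flexibility signal.

### Interfacial atoms: β contacts plus a local-contact rule

A cross-unit atom pair (i, j) is a β contact when all three hold:

1. d(i,j) < Td + vdw(i) + vdw(j), Td = 2.8 Å by default (a
   water-diameter slack; exposed as a parameter since published uses of
   β contacts do not pin it);
2. the two atoms share a Voronoi facet in the diagram of the whole
   complex;
3. the forbidden region is empty: no third atom k has ∠ikj ≥ ∠β.
   ∠β = 90° by default, making the region the open diametral sphere of
   the segment — the Gabriel-graph criterion, which also admits an exact
   combinatorial oracle for testing.

Facet sharing is computed through Delaunay duality (in general position,
cells share a positive-area facet iff the sites are Delaunay-adjacent).
scipy/Qhull's direct Voronoi ridge output was found to drop hull-adjacent
ridges that are genuine Delaunay edges, so the dual route is both faster
and more faithful.  General position is enforced by a deterministic
~1e-9 Å perturbation keyed to atom order: cospherical degeneracies (and
with them zero-area facets) are resolved identically on every run.  The
forbidden-region scan restricts candidate blockers to a ball of radius
|ij|/sin∠β around an endpoint (law of sines bound), making the test
local.  Blockers are atom centers; hetero atoms block by default but are
never interfacial candidates; waters and hydrogens are removed entirely.

An atom with at least one β contact is kept as interfacial only if its
*local* contact count — β contacts of itself plus of atoms within two
covalent-bond steps — exceeds 2.  This prunes isolated touches.  Covalent
bonds are inferred from summed covalent radii + 0.4 Å, restricted to
chemically plausible topology (same residue, peptide C–N between
consecutive residues, S–S ≤ 2.3 Å).  "Local contacts" counts β contacts
only, not plain distance contacts: the definition appears immediately
after β contacts are introduced and no other contact notion is in scope
at that point.

### Features

ΣB sums b_norm over the interfacial atoms of *both* units; No.B counts
those with b_norm < 0 (strictly — atoms exactly at the unit mean are not
"rigid").  Both are divided by log(min_r + 1) to give avgΣB and avgNo.B,
where min_r is the smaller of the two units' mean residues-per-chain;
the logarithm damps the size correction for very large units, and the
natural base is used (the base is a free convention that rescales both
classes identically and cannot affect threshold-based classification; it
matters only when comparing absolute values across implementations, so
it is exposed as `log_base`).  The compound score is
avgNo.B · avgΣB / 100.  A zero-atom interface yields all-zero features
with an `empty_interface` flag rather than an error — vanishing
interfaces are evidence of packing, not a failure mode.

### Interface area baseline

ΔASA = (ASA₁ + ASA₂ − ASA_C)/2, with avgΔASA sharing the log(min_r+1)
denominator.  SASA is Shrake–Rupley: each atom's probe-inflated sphere
(probe 1.4 Å) is sampled on a fixed golden-spiral lattice (960 points by
default; 3840 in convergence checks changes slab-interface ΔASA by
< 1%), and a point is accessible when no neighbouring inflated sphere
contains it.  Sample points falling exactly on a neighbour's surface are
assigned to the lower-index atom so coincident spheres count their shared
surface once.  The lattice is deterministic, so equal inputs give equal
areas to machine precision; rigid-motion invariance holds only to ~1%
because the lattice orientation is fixed in space.  vdW radii: C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, default 1.70 Å, overridable by config.

### Threshold learning and evaluation

Candidate splits are midpoints between consecutive distinct sorted
scores — a finite set that realizes every possible labelling partition.
Each split is scored by MCC in both decision directions; the top
ceil(0.10·n_splits) splits by best-direction MCC (ties at the cut
included) are averaged into the threshold, and the majority direction
among them is adopted.  Averaging the best decile rather than taking the
argmax trades a sliver of training MCC for stability.  An alternative
reading of "top 10%" — all splits within 10% of the best MCC — is
available as `mode="within_best"`.  Note an intrinsic limit: MCC depends
only on ranks, so the *kept split intervals* and direction are exactly
invariant under monotone score transforms, but the arithmetic mean of
split values is not rank-equivariant — under a strongly nonlinear
transform the averaged threshold can land one data gap away, flipping
borderline predictions.  Tests assert the exact rank-level invariants.

Positives-only training data (e.g. affinity-annotated complexes with no
packing negatives) use the empirical q-quantile of the scores
(q = 0.25, linear interpolation / type 7) with caller-supplied
direction.  Metrics follow the standard confusion-matrix definitions
with biological = positive; any zero denominator in MCC yields 0.

Entry-level quality rules for dataset compilation (X-ray method,
resolution < 2.5 Å, atoms ≥ 3× residues, both partners > 5 residues,
non-standard-residue contact fraction < 20%) are implemented as a pure
predicate returning every violated rule.

## Synthetic data: what it emulates and what it does not

The generator builds two-unit complexes whose *statistics* mimic the
empirical signal.  Each residue is a bonded 4-atom zig-zag chain (1.5 Å
steps, so the inferred bond graph is a path per residue — without this
covalent structure the local-contact rule degenerates to counting an
atom's own contacts only); residue centers sit on a 3.5 Å jittered
lattice shaped into slabs meeting at z = 0 ("slab-contact", gap 1.6 Å),
touching spheres, or 100 Å-separated clusters.  Raw B factors are drawn
per unit with mean ~25–45 Å² and sd ~8–12 Å² (typical X-ray scales), so
Eq-style normalization is exercised non-trivially.  The planted effect —
"interface-rigid" — shifts B factors of atoms within 4 Å of the contact
zone down by `interface_rigidity` unit-standard-deviations; the default
effect size is 1.0.  Units are serialized to PDB text and re-read
through the standard loader, so every end-to-end run also exercises
structure I/O at PDB column precision (coordinates 10⁻³ Å, B 10⁻² Å²).

Not emulated: real residue chemistry and packing density, crystal-lattice
symmetry, correlated B-factor structure (TLS), peptide connectivity
across residues, or the size diversity of real benchmark datasets.
Passing the end-to-end test therefore shows that the pipeline *recovers a
planted rigidity signal of realistic magnitude through the full
geometric/statistical machinery* — not that real biological and packing
interfaces are separable at any particular accuracy.

## Problem sizes and numerical choices

Default study conditions for the end-to-end experiment: 50
interface-rigid vs 50 uniform complexes, 240 atoms (60 residues, 2
chains) per unit, evaluated by two-fold cross-validation with
interleaved folds, plus a 10-permutation label-shuffle null.  Geometry
oracle checks use 50 random point sets (Gabriel up to n = 60;
empty-circumsphere Delaunay enumeration up to n ≈ 24, where the O(n⁴)
oracle is still fast).  Degenerate inputs: fewer than 5 points or
coplanar sets raise geometry errors; coincident blocker atoms raise
rather than silently passing; all-equal scores refuse threshold
learning.

## Known limitations

* B factors are deposition-dependent (refinement protocol, resolution,
  TLS parameterization); cross-entry comparability rests entirely on the
  per-unit normalization.
* Td and ∠β defaults are conventional, not fitted; results on real
  entries shift with them, and the worked-example agreement tolerance is
  set accordingly (±5%).
* The SASA engine behind published ΔASA values is unspecified in
  general; absolute agreement beyond ~3% between engines is not
  expected.
* Assemblies are built from REMARK 350 operators only; no space-group
  symmetry expansion is attempted, and NMR/EM entries are out of scope.
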