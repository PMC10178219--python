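# Methods

## Pocket definition and generic numbering

A class A GPCR binds its endogenous ligand in a cavity between the
seven transmembrane helices, open to the extracellular side.  The
package identifies pocket positions by generic residue numbers: the
Ballesteros–Weinstein label `h.bb` (helix, position relative to the
most conserved residue = 50) extended with the GPCRdb structural
position after an `x` (`2.57x56`), which corrects for helix bulges and
gaps so that one label denotes the spatially equivalent residue in any
receptor.  The canonical machine token is lowercase-`x` without spaces;
the typographic form with a multiplication sign (`2.57 × 56`) is
accepted on input only.  One bundled position, `5.46x461`, carries a
three-digit structural part; it is preserved verbatim rather than
reinterpreted, since the bulge nomenclature admits both readings.

Two residue sets ship as defaults:

* **Surrogates** (10): `2.57x56 2.65x64 3.28x28 3.37x37 5.38x39
  5.47x47 6.51x51 6.58x58 7.32x31 7.43x42` — the highest and lowest
  frequently ligand-contacting position on each of TM2/3/5/6/7.  TM1
  and TM4 do not line the pocket and are excluded.
* **Restraint tetrahedra** (4+4): tetrahedron 1 = `2.60x59 3.40x40
  5.38x39 7.32x31`, tetrahedron 2 = `2.65x64 4.57x57 5.46x461
  6.48x48`.

The extended pocket-lining census is nominally 34 residues.  The full
list is a user-supplied configuration (pocket-definition file with
`[surrogates]/[tetra1]/[tetra2]/[extended]` sections); the bundled
default for `extended` is the 15-position union of the sets above,
which is what the restraint machinery itself needs.  Mapping a generic
number to a concrete residue is a per-receptor table (TSV), typically
derived from GPCRdb's numbering service; the package performs no
sequence alignment of its own.

## Volume measurement

The pocket volume is the volume enclosed by the Cα atoms of the ten
surrogate residues: the points are tessellated by Delaunay
triangulation (scipy's Qhull) and the simplex volumes
|det(v₁−v₀, v₂−v₀, v₃−v₀)|/6 are summed.  For a finite 3-D point set
this sum equals the convex-hull volume, which the test suite verifies
to 1e−9 relative tolerance against an independent hull computation.
Cα coordinates are used so the same measurement works in backbone-only
(centroid) and all-atom models and is indifferent to side-chain
identity.  No alpha-shape carving or cavity-ball construction is
applied; with ten roughly convex-position points the hull is the
intended measure, and concave-pocket methods are deliberately out of
scope.  Configurations with fewer than four points or with third
singular value ≤ 1e−8 Å (coplanar/collinear) raise a degenerate-
geometry error rather than returning 0, so silent garbage can never
enter a volume filter.  Tetrahedron volume from six edge lengths uses
the Cayley–Menger determinant (288 V² = det CM); determinants below a
scale-aware threshold (1e−12 · (mean squared edge)³) are reported as
non-realizable.

Superposition RMSD uses the Kabsch solution restricted to proper
rotations (det = +1), matched by point label; Biopython's
SVDSuperimposer serves as an independent oracle in the tests, never as
the implementation.

## Distance knowledge base and contact detection

Per-pair Cα–Cα statistics over a structure census record n, median,
mean and the population (n-denominator) standard deviation — a
descriptive statistic over the available census, not an inference to a
larger population; the median of an even count is the mean of the two
middle values.  A structure that cannot resolve one mapped position
still contributes to every pair it can measure, with per-pair n
recording the effective census.  Ligand contacts use heavy atoms only
on both sides (hydrogens are rarely resolved crystallographically) and
a closed 3.5 Å ball: a residue exactly at the cutoff is a contact.
Contact-frequency ranking across structures breaks ties by canonical
generic-number order for determinism.

## Restraints

Each tetrahedron edge (i, j) becomes a Rosetta AtomPair restraint

    f(d) = A · ( ((d − C)/B)² + D )

with a single parameter draw shared by the six edges of a tetrahedron
and drawn independently for the two tetrahedra of a set:

| parameter | meaning | range | default sampling |
|---|---|---|---|
| A | restraint weight | {2, 3, 4} | uniform integer |
| B | harmonic steepness (Å) | [0.4, 0.8] | uniform, 0.1 grid |
| s | reference inflation | [1.03, 1.07] | uniform, continuous |
| D | score offset | {−10, …, −1} | uniform integer |
| C | reference distance (Å) | s · d_ref | derived |

d_ref is either the knowledge-base median for the edge (bundled
reference table; knowledge-base mode) or the Cα distance measured in a
supplied template structure (template mode).  The 3–7 % inflation s
biases the restraint minimum slightly outward to counteract relaxation
shrinkage; the negative offset D makes a satisfied restraint lower the
total score, so restrained models are not penalized relative to
unrestrained ones.  Gridded sampling (B to one decimal, integral A and
D) matches the granularity worked restraint files exhibit; continuous
B sampling is available behind a flag.  The emitted line format is

    AtomPair CA <i> CA <j> SCALARWEIGHTEDFUNC <A> SUMFUNC 2 HARMONIC <C> <B> CONSTANTFUNC <D>

with single spaces, C to 4 decimals, B to 1 decimal, A and D integral,
tetrahedron-1 edges first, edges ordered (v1v2, v1v3, v1v4, v2v3,
v2v4, v3v4) by the bundled vertex order.  HARMONIC takes the center
first and the steepness second, consistent with Rosetta's function
syntax.  The parser tolerates typesetting-damaged spacing (`CA66`,
`SUMFUNC2HARMONIC`, `CONSTANTFUNC-8`) but never emits it, and rejects
unknown function names with the line number.

## Ensemble filtering and classification

Observed pocket volumes of repeatedly determined receptors vary by
roughly ±100–200 Å³ within one activation state, so ±200 Å³ is treated
as the natural variation band.  For each receptor's ensemble the
median volume is taken over all models and models with
|V − median| ≤ 200 Å³ pass (closed interval); survivors are ranked by
total score, ties broken lexicographically by label, and the best five
kept.  Ranking is by energy only after the volume filter — applying a
secondary volume sort after energy is a documented alternative reading
but is not done here.  A model-versus-reference volume difference is
classified as within natural variation (|Δ| ≤ band), deviating
(shrunken or enlarged, up to 3× the band) or a failed pocket
construction beyond that; both thresholds are configurable.  Docking
post-processing counts interface scores ≤ −6 REU (boundary inclusive)
as successful poses.

## Structure I/O policies

PDB parsing and writing go through gemmi.  Defaults: first chain with
≥ 100 polymer residues (receptor-sized; fusion partners and stubs on
other chains are skipped), falling back to the largest chain; altloc
keep-first (deterministic; keep-highest-occupancy available and
identical when occupancies tie); first MODEL only; hetero exclusion of
waters and common ions/additives (HOH DOD NA CL K MG ZN CA SO4 PO4 GOL
EDO PEG) — membrane lipids and detergents are kept because they can
occupy the pocket and count as bound ligands.  Hetero groups are
collected from every chain regardless of chain policy, since ligands
often sit on their own author chain.  Polymer residues lacking a Cα
are dropped with a warning (strict mode raises); retained residues get
pose numbers 1..N in file order, the numbering constraint files use.
The `SCORE:` table reader takes the first such line as the header,
requires a `description` column, and lets the last duplicate label win
with a warning.

## Synthetic fixtures

The generator builds an idealized 7TM Cα bundle: helix axes on a
circle of radius `pocket_radius`, antiparallel neighbors, textbook
α-helix geometry (rise 1.5 Å/residue, twist 100°/residue, Cα helix
radius 2.3 Å), 40 residues per helix, all-ALA, Cα-only.  Generic
positions are planted at fixed per-helix indices and emitted as a
normal mapping TSV, so the numbering path is exercised identically to
real data.  The default radius (8.35 Å) is chosen so the surrogate
pocket volume lands near 2600 Å³, the typical inactive-state class A
value; seeded Gaussian jitter emulates census heterogeneity.  Planted
ligands place one carbon atom per target residue at the contact
distance, choosing for each atom the direction (over a deterministic
200-point Fibonacci sphere) that maximizes clearance from all other
residues, and verify the planted truth before returning.  Ensembles
draw volumes from N(2600, 200²) Å³ — matching the observed census, in
which ~68 % of receptors fall within 2600 ± 200 Å³ — with independent
normal total and interface scores.

What the fixtures do *not* emulate: side chains, loops, membranes,
sequence variation, realistic energetics, and the tight packing of a
real bundle (the planted surrogate positions span more of the helix
length than a real pocket does, and the default radius is set by
pocket volume, not by helix-packing distances).  Tests passing on
fixtures therefore demonstrate the correctness of the geometry,
numbering, statistics, restraint and filtering machinery — not the
biophysical accuracy of any modeling protocol built on top of it.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: censuses
of ≤ 25 jittered bundles, ensembles of 100 models (the standard
modeling batch) and 10 000 models for the pass-rate-versus-normal-law
check, 100-repetition property loops, and 1000 parameter draws.  All
randomness is numpy `default_rng` under explicit seeds; the acceptance
script derives independent sub-streams from a single `--seed` via
`SeedSequence.spawn`.  Volumes of real experimental structures require
the PDB entry plus a GPCRdb-derived mapping table; `gpcrpocket.fetch`
automates both where network access exists, and the corresponding
checks fail cleanly without it.

## Known limitations

* The full 34-residue pocket census is not bundled; combinatoric
  checks on it use 34 labeled points, and users supply the full list
  via a pocket-definition file when they have one.
* GPCRdb numbering is reported against UniProt positions;
  `fetch_gpcrdb_residue_map` assumes author numbering matches UniProt
  numbering on the receptor chain, which holds for most crystal
  structures but not all constructs — supply a hand-curated mapping
  TSV where it does not.
* Only class A (`h.bbxgg`) numbering is supported; classes B/C/F use
  different schemes.
* mmCIF input, multi-model ensembles in one file, and
  occupancy-weighted coordinates are not supported.
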