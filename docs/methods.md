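# Methods

## Scope and model

The package measures where a class A GPCR conformation sits between an
inactive and an active reference, using only coordinates. It does not run
or require molecular dynamics; frame series are consumed as multi-model PDB
snapshots (or generated synthetically). All geometry is rigid-body: there
is no force field, no energetics, and no flexible fitting.

Residues are addressed by Ballesteros–Weinstein generic numbers through an
explicit label → (chain, residue number) table supplied by the user (or by
the synthetic generator). Automatic numbering assignment from sequence is
deliberately out of scope, as is any guess about which chain of a
multi-chain model to analyze — the chain is always explicit.

## Geometry kernel

* **Superposition** is Kabsch via SVD with the determinant correction (the
  smallest singular vector is flipped when the optimal orthogonal matrix
  would be a reflection), so the result is always a proper rotation
  minimizing RMSD. Point sets with fewer than 3 points, or whose second
  singular value vanishes (collinear/coincident), raise a geometry error
  because the rotation is underdetermined.
* **Dihedrals** follow the IUPAC sign convention (cis = 0°, trans = 180°,
  positive = clockwise rotation of the far bond viewed from atom 2 toward
  atom 3), wrapped into (−180°, 180°]. Note the identity that a torsion is
  *invariant* under reversing the atom order; the sign flips under mirror
  reflection. χ1 is N–Cα–Cβ–γ; χ2 is Cα–Cβ–γ–δ, with the tryptophan χ2
  taken on Cδ1. Alanine/glycine raise a dedicated no-χ error, which is how
  an alanine-substituted toggle position (the F→A/W→A double-mutant case)
  is detected and the classifier declared inapplicable.
* All angle comparisons are circular (wrapped differences), and all
  distances are plain Euclidean in Å.

## Indicators and state calls

The built-in CB1 set attaches published reference distances where they
exist: Y5.58–Y7.53 (Oη–Oη) 10.5/3.4 Å and TM3–TM6 (3.50–6.34 Cα) 8.2/13.8 Å
(inactive/active). The two N-terminal indicators carry no active reference
— the probe phenylalanine is typically unmodelled in active structures —
and evaluate to NaN (a flagged missing value, not an error) when the probe
residue is absent. "Main-chain O" is the backbone carbonyl oxygen named
`O`; the tyrosine η-oxygen is the PDB atom `OH` (a small alias table maps
alternative spellings).

State calls compare a per-frame value against both references with a
default tolerance of 1.0 Å (configurable). The default reflects that the
two CB1 reference pairs are separated by 5–7 Å, so a ±1 Å band labels
frames confidently while leaving a wide intermediate zone; when both
references match the nearer one wins and an exact tie is intermediate.

## Twin-toggle-switch classifier

A frame is reduced to four features: χ1(3.36), χ2(6.48), a positional-swap
flag, and the 6.48 Cα slide. The slide is measured *from the active-state
position* (frame and active reference both superposed on the inactive
reference's TM3 Cα atoms): it is 0 for the active structure and equals the
full inter-state displacement for the inactive structure, so "slid beyond
threshold" means the backbone has left the active position. The swap flag
projects the 3.36→6.48 ring-centroid vector onto the inactive reference's
bundle principal axis (the membrane normal, computed by PCA of the Cα
cloud) and reports whether the order is inverted relative to the reference
— the geometric content of "the two residues still occupy each other's
positions".

Classification is nearest-centroid on the (χ1, χ2) torus with the L∞
metric, so wells are square windows, matching how rotamer clusters appear
in χ1/χ2 scatter plots. Defaults: window 40° (canonical rotamer wells are
~120° apart, leaving a ~40° margin between windows), slide threshold 2.0 Å
(well above coordinate noise, well below the ~6.8 Å inter-state slide).
Centroids are measured from the two reference structures at table
construction rather than hard-coded; the novel "pushed" χ2 well defaults to
the inactive 6.48 rotamer displaced by +120° (one rotamer step), and all of
these are configurable. The decision order is: dihedral match to a well
(inactive well splitting on the swap flag into inactive vs
reversed-inactive), then the sliding rule (active-like χ1, χ2 outside all
wells, slide beyond threshold), then the pushed χ2 region, else unassigned.
The rule is total and deterministic.

The active ratio pools frames across runs by frame count by default
(per-run averaging is available as a flag); pooling is the natural reading
of counting a configuration "through all the simulations", and the two
conventions agree when runs have equal length.

## Contact score

RRCS defaults are d_full = 3.23 Å, d_zero = 4.63 Å, sequence-separation
cutoff 4 with backbone atoms {N, CA, C, O} excluded for near pairs — the
parameterization of the contact-score method as commonly applied; the
defaults are configurable and echoed into output metadata. Hydrogens are
always excluded, and occupancy weighting is not applied because the reader
resolves alternate locations to a single conformer (highest occupancy, ties
toward altloc A). The score is exactly reproduced by a brute-force
double loop in tests; it is continuous in coordinates with Lipschitz
constant (number of qualifying pairs)/(d_zero − d_full).

## 7×7 matrix

Row r, column j: superpose structure B onto A using helix r's Cα atoms,
then take the Cα RMSD of helix j *without re-fitting*. The diagonal is the
column minimum by construction (aligning on a helix minimizes its own
RMSD), and the matrix is symmetric under swapping the two input structures
because the inverse of the optimal transform is the optimal transform of
the swapped problem. Helix pairing is by residue number within the segment
ranges; residues modelled in only one structure are trimmed symmetrically
with a warning, which is the pragmatic choice for deposited models with
differing resolved termini.

## Synthetic generator

The generator emulates just enough receptor geometry for every stage to be
exercised with known truth, on CB1-like author numbering (3.50 = 214,
6.48 = 356, …):

* seven ideal α-helices (NeRF-built backbone at φ = −57°, ψ = −47°; rise
  ≈ 1.5 Å/residue) on an 11 Å circle, TM3 at 5 Å radius near the core;
* the inactive state tilts TM6's cytoplasmic end toward TM3 until the
  3.50–6.34 Cα distance is 8.2 Å; the active state solves a hinge tilt plus
  axial slide jointly so that distance is 13.8 Å *and* the 6.48 Cα moves
  6.8 Å from its inactive position (TM3 aligned). TM7 is levelled and
  tilted toward Y5.58 per state to put the hydroxyl pair at 10.5/3.4 Å.
  All solves are Brent/least-squares at build time, verified to 0.1 Å,
  and fully deterministic;
* side chains at the special positions are built from ideal internal
  coordinates, so requested χ angles are exact (no rotamer library).
  Defaults: 3.36 Phe χ1 150° (inactive) / −60° (active), 6.48 Trp
  (χ1, χ2) = (60°, 90°) in both states — the Trp keeps one rotamer across
  the reference states, the Phe changes rotamer, the pair is in heavy-atom
  contact (≈3.8 Å) only in the inactive state, and the ring centroids swap
  order along the bundle axis between states, reproducing the qualitative
  twin-toggle geometry;
* an N-terminal probe Phe sits inside the extracellular pocket (inactive)
  or far outside the bundle (active); TM1/TM2 shift inward by 1.5/2.0 Å in
  the active state.

Trajectories hold state coordinates, bridge different states by linear
Cartesian interpolation, and add i.i.d. Gaussian coordinate noise from a
seeded generator (bit-identical under a fixed seed). An optional χ-jitter
mode rotates the toggle side chains about their χ1/χ2 bond axes by normal
deviates, giving exactly controlled angular noise for classifier tests.
Ground truth records per-frame state labels, toggle labels (bridge frames
are unassigned and excluded from recovery scoring), and scheduled
transition midpoints.

What passing on synthetic data does **not** show: robustness to real
side-chain packing, loop flexibility, missing density, alternate
conformer ambiguity beyond the single-conformer policy, or MD force-field
artifacts. The generator has no sterics and no membrane; its value is
exact, known truth, not physical realism.

## Problem sizes and numerics

Tests and the acceptance script use 500-frame trajectories for classifier
recovery, 100 random residue pairs for the RRCS oracle, and 1000 random
rotations for the superposition optimality check — sizes chosen so the full
suite completes in well under a minute while keeping the statistical checks
meaningful. Superposition agreement tolerances are 1e-6 Å (and 1e-9 Å
against closed-form oracles); angle constructions are verified to 1e-3°.

## Known limitations

* mmCIF and binary trajectory formats are not read; inputs are PDB text.
* The deposited-structure acceptance check requires the user to download
  the two CB1 reference entries; the package does not fetch or bundle them.
* The classifier's well boundaries are declared defaults, not fitted to
  any empirical χ distribution; with references whose rotamers are closer
  than ~2× the window the wells would overlap and should be narrowed.
* Insertion codes are carried through residue keys but the generic-number
  map addresses (chain, residue number) with an empty insertion code.
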