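# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis, what the synthetic test structures do and do not
emulate, and the known limitations.

## Coordinate model and parsing

Coordinates are Ångström throughout; residue numbering is the author
numbering from the file, and ranges are inclusive on both ends. Parsing is
delegated to gemmi's fixed-column reader. Alternate locations are resolved
at parse time: the highest-occupancy conformer is kept, ties going to the
lexicographically first alt-loc id. Same-named chain segments separated by
TER (the PDB convention for ligands and waters following a polymer) are
re-merged so chain ids remain unique within a model. Only model 1 is used
by analyses unless a model index is passed. Hydrogens are parsed but all
analyses are defined on heavy atoms. A concatenated multi-entry file
(entries separated by END records) is read into a single container whose
parts keep distinct structure ids, so selections can address
(structure, chain); the same container is produced by appending parsed
structures programmatically.

## Interaction detection

All six interaction types are distance rules between heavy atoms, with
defaults hbond 3.8 Å, salt bridge 6 Å, contact 4 Å, halogen 3.8 Å,
pi-cation 6 Å, pi-stacking 5.5 Å. There are no angular criteria: hydrogen
positions are not modelled, so donor/acceptor geometry beyond the
heavy-atom distance is unknown. This admits some geometrically impossible
hydrogen bonds; it is a deliberate simplification, and the donor/acceptor
tables (backbone N/O plus the usual side-chain N/O/S groups) are this
package's own. Histidine is neutral by default — at pH 7 its standard pKa
leaves it mostly unprotonated — with a `his_charged` flag to treat ND1/NE2
as cationic. Tryptophan's five- and six-membered rings get separate
centroids. One interaction per (type, residue pair) is reported with the
closest qualifying atom pair; a contact is reported for a residue pair
already carrying a specific type only if some atom pair within 4 Å is not
part of that specific interaction, which lets contacts and hydrogen bonds
coexist between the same residues without double-counting atoms.

## Mutation engine

The mutant side chain is grown on the unchanged backbone (N, CA, C, O are
never touched) with ideal internal geometry taken from the chemical
component dictionary shipped with biotite, converted into a chi-
parameterised placement recipe. The rotamer library is deliberately small —
three to nine canonical chi combinations per residue type with rough prior
weights — because single-residue repacking against a rigid environment is a
clash-resolution problem, not a packing prediction problem. The score is a
soft steric overlap, `sum over side-chain/environment heavy-atom pairs of
((rvdw_sum - d)/rvdw_sum)^2` for d below the van-der-Waals contact
distance, plus `-log(library weight)`; environment atoms further than 16 Å
from the site CA are ignored. After the exhaustive library pass the best
rotamer is refined by coordinate descent: each chi in turn moves in
2-degree steps for as long as the score strictly decreases, capped at 90
sweeps (one full turn per chi). The procedure is deterministic, the score
trajectory non-increasing by construction, and the refinement degenerates
gracefully: on a flat landscape (no clash anywhere) no step improves and
the library rotamer survives unchanged. Neighbouring side chains are not
repacked, the backbone does not relax, and the score has no physical energy
scale — gained/lost interaction lists, not energies, are the product.
Proline is built from its fixed template dihedrals; its ring closure onto N
is approximate on non-ideal backbones.

## Superposition

Kabsch via SVD with the usual determinant-sign correction, so mirror inputs
still return a proper rotation. Sequence-guided mode aligns chain sequences
with Needleman–Wunsch under BLOSUM62, gap open −11 / extend −1 (the
standard protein defaults; nothing in the analyses depends strongly on
them) and superposes the CA atoms of matched pairs, optionally restricted
to a master residue range. Residue-by-residue mode pairs ranges
positionally and demands equal CA counts. CA-only superposition is the
conventional reduction; full-atom fitting is out of scope, as is any
purely geometric (sequence-free) alignment.

## Symmetry scan

The selection's CA trace (at least 8 residues, at most 30,000 atoms) is
aligned to itself under every circular shift k from 4 to N−4. The
correspondence is pinned to the shift — residue i pairs with i+k mod N —
and refinement only selects which of those pairs survive: Kabsch on the
surviving subset, deviations recomputed, pairs within a 3.5 Å capture
radius kept, iterated to stability (max 10 rounds). Freeing the
correspondence (nearest-neighbour re-pairing) was tried and rejected: every
shift then collapses onto the same symmetry transform and the score
distribution saturates. The shift score is the number of residues within
3 Å after superposition. Significance is a z-score of the best shift
against the score distribution using median and MAD (scaled by 1.4826)
rather than moments: a Cn symmetry produces n−1 high-scoring shifts, which
would inflate a standard deviation and mask the very signal being tested;
the MAD ignores them. The sigma is floored at one residue so near-constant
score lists cannot manufacture unbounded z. A symmetry is accepted only
above z = 8. The winning transform is decomposed into rotation angle, axis
(the rotation eigenvector, oriented so the rotation is positive) and screw
rise (translation component along the axis); if 360/angle rounds to an
integer order ≥ 2 within 10° and the rise is under 2 Å the call is cyclic,
otherwise helical. Ties between equal-z shifts go to the smallest shift.
The z values are this package's own calibration and are not comparable
numerically with other symmetry programs — only the categorical calls
(order, found/not found) are.

A practical note baked into the test design: monomers with strong internal
self-similarity (ideal helices are screw-symmetric) add secondary peaks to
the scan; the robust statistics handle them, but the ring fixtures used in
the recovery tests are built from 16-residue seeded coils, which have no
internal symmetry, so that the test isolates ring-order recovery from
monomer self-similarity. A 16-residue monomer is the smallest for which
the shift-score distribution is stable enough to give z margins well clear
of the threshold.

## Electrostatics

The linear Poisson–Boltzmann equation, in kT/e units with lengths in Å and
charges in e:

    div(eps(r) grad phi) − eps_out · kappa²(r) · phi = −4π · l_B · q(r)

with l_B the vacuum Bjerrum length e²/(4π ε₀ kT) ≈ 560.7 Å at 298 K and
kappa² from the 1:1 salt concentration (0.15 M default, Debye length
7.9 Å). 1 kT/e = 25.693 mV at 298 K. Discretization is a 7-point stencil on
an n³ grid (n = 65 default, odd, ≥ 17); the box is sized so the molecule
spans 70% of it unless given explicitly, charges are spread trilinearly to
the eight surrounding nodes, and the Dirichlet boundary is the superposition
of per-charge Debye–Hückel monopoles — per-charge rather than a single
total-charge monopole so that the solution is exactly linear in the charge
set, which the linearity test exploits. Face dielectrics are harmonic means
of node values, and node dielectric values are anti-aliased across one grid
spacing at the probe-inflated (1.4 Å) molecular boundary: a hard staircase
boundary makes the reaction field of buried charges visibly grid-dependent,
and the smoothing removes most of that sensitivity. Pointwise convergence
exactly on the dielectric interface is still not expected, so grid-
comparison checks sample a solvent-side shell ~1 Å off the surface. Ions
are excluded from a Stern layer (atom radius + 2 Å); the uniform-medium
oracle test disables the exclusion because the Debye–Hückel closed form
assumes salt everywhere. The system is solved by Jacobi-preconditioned
conjugate gradients to a 1e−6 relative residual (the operator is symmetric
positive definite).

Charging is formal and heavy-atom only: Asp/Glu −0.5 per carboxylate O,
Lys +1 on NZ, Arg +1/3 on NE/NH1/NH2, His 0, nucleotide phosphates −0.5
per non-bridging O; optional termini add +1 on the first N and −0.5 on
O/OXT when OXT is present (so totals stay integral). No hydrogens are
added and no partial-charge force field is used — potentials are
qualitative surface maps, not energies. eps_in 2 / eps_out 80 / probe
1.4 Å are conventional continuum-electrostatics defaults and configurable.
Surface classing samples 42 golden-spiral points per atom on probe-inflated
spheres, keeps exterior points, interpolates trilinearly and classes
against ±50 mV.

## Contact maps and cartoons

Contact comparison is ≤ threshold, inclusive, for boundary determinism;
glycine (and any residue lacking CB) is represented by CA in C-beta mode,
residues lacking the representative atom are dropped with a warning, and
multi-chain selections are ordered chain-major with inter-chain contacts
included. Secondary structure is assigned from backbone dihedrals alone
(helix: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°], run ≥ 4; strand:
φ ∈ [−180°, −60°], ψ ∈ [60°, 180°] ∪ [−180°, −150°], run ≥ 3) — chosen
over hydrogen-bond-pattern methods because no hydrogens are modelled
anywhere in the package; it agrees with ideal-geometry fixtures exactly and
will disagree with DSSP on distorted real structures. Oval glyphs take
their orientation from the first principal axis of the projected CA
coordinates and their size from the square roots of the principal
variances (1 drawing unit per Å of standard deviation); the principal-axis
sign ambiguity is resolved toward increasing residue number.

## Synthetic structures: what they show and what they do not

All fixtures are grown from ideal backbone geometry (the standard bond
lengths/angles) by the same placement primitive the mutation engine uses,
so their advertised properties hold exactly and every oracle is analytic:
helices have their i→i+4 carbonyl–amide distances under 3.5 Å, Cn rings
are exactly invariant under 360/n rotations before jitter, engineered
interfaces place each requested interaction at a distance safely inside
its threshold with no unrequested specific interaction, and seeded coils
are self-avoiding by construction. Two larger stand-ins are labelled
synthetic in name and docstring: a receptor/binder complex whose interface
carries exactly two salt bridges and whose binder position 501 gains one
pi-cation and one pi-stacking interaction upon Asn→Tyr rebuilding, and a
single chain whose residues 1–178 form two C2-related lobes with an
asymmetric tail. They exercise the full parser → detector → mutation →
symmetry pipeline end to end on literature-shaped problems, but they are
constructed geometry: passing on them demonstrates the algorithms, not
agreement with any deposited experimental coordinates, and real structures
bring disorder, alternate conformations, waters and non-ideal geometry
that the fixtures deliberately omit.

## Problem sizes

The test suite and the acceptance script run on deliberately desk-scale
problems: 12–60-residue fixtures, 16-residue ring monomers (30 ring
detections), 178-residue symmetry scans, and PB grids of 33³–97³ with one
65³ solve against the closed form. These sizes keep every check exact or
near-exact while the whole suite completes in well under a minute of
compute per module; the algorithms themselves have no size assumptions
beyond the symmetry module's 30,000-atom cap.

## Known limitations

* No hydrogen placement anywhere; all criteria are heavy-atom based.
* Interaction rules are distance-only (no angular cones for hydrogen or
  halogen bonds, no cation–π geometry beyond centroid distance), and
  water-mediated interactions are not modelled.
* The mutation engine repacks a single residue against a rigid
  environment; no ΔΔG, no backbone motion.
* The symmetry z-score is a package-specific calibration; only categorical
  calls are portable.
* The PB solver is linear, formal-charge, and qualitative; no pKa shifts,
  no nonlinear response, no focusing.
* Dihedral-basin secondary structure is coarser than hydrogen-bond-pattern
  assignment on real, distorted structures.
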