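# Methods

This note records the model, the algorithms, the tunable parameters and
the design choices behind `symadapt`, in the order the pipeline runs.

## Equivalence sets

Atoms are partitioned into orbits of symmetry-equivalent nuclei *before*
any symmetry element is known, by clustering per-atom quantities that
are invariant under every isometry permuting equal-mass atoms:

* mean and euclidean norm of the atom's row of the reduced-mass weighted
  distance matrix `D_ij = μ_ij |a_i − a_j|`, `μ_ij = m_i m_j/(m_i+m_j)`,
  with coordinates relative to the centre of mass;
* the norms of the unit-sphere projection `s_i = Σ_j μ_ij d_ij/|d_ij|`
  and the plane projection
  `p_i = Σ_j μ_ij (a_j − (a_i·a_j/|a_i|²) a_i)`.

Element symbol and mass are hard keys (the optional fifth XYZ column
overrides the bundled standard atomic weight, so isotope substitution
splits orbits exactly).  Clustering is single-linkage: two atoms link
when all four components agree within `rel_tol` (default `1e-3`)
relative to the component's scale.  Two refinements matter in practice:

* **Scale floors for the projections.**  In highly symmetric
  arrangements `s_i` and `p_i` cancel to zero (the plane projection is
  identically zero for a staggered sandwich), so under coordinate noise
  their relative values are pure noise.  Each projection's comparison
  scale is therefore floored at 20 % of its triangle-inequality bound
  (`Σμ` and `Σμ|a_j|`).  Without the floor, a mÅ-noised orbit splinters
  into antipodal pairs.
* **Noise-coupled tolerance.**  Detection at geometric tolerance `tol`
  implies coordinate uncertainty of order `tol`; the pipeline widens the
  clustering tolerance to `max(rel_tol, 2·tol/R_rms)` (capped at 0.1,
  `R_rms` the RMS distance from the centre).  Over-merging two true
  orbits is harmless — a symmetry operation permutes their union, so
  validation still succeeds — whereas splitting one orbit loses its
  candidate elements.

The partition is refined recursively: each subset is re-analysed as its
own point set (about the unchanged molecular centre) until a fixed
point.  Refinement only ever splits, so it terminates.

An alternative per-atom invariant (the inertial-tensor eigenvalues about
each atom) is not used; the four properties above proved sufficient for
every supported family.  The full `D` matrix is O(N²) memory; the sizes
this package targets (≤ a few thousand atoms) fit comfortably, so no
streaming fallback is implemented.

## Symmetry elements

Each equivalence set proposes candidate elements from its own inertial
frame (unit masses; eigen-decomposition by a cyclic 3×3 Jacobi sweep):

* **Every principal axis**: rotation orders are read off ring
  populations — points grouped by (height, radius) about the axis; the
  cyclic group acts freely off-axis, so its order divides every ring
  size, and the divisors of the gcd are tested largest-first.  There is
  no ceiling on the order, which is what makes D₄₇d detection the same
  code path as D₆d.  A mirror normal to each axis and the improper
  orders `n`, `2n` are tested too.
* **Degenerate (symmetric-top) axes**: perpendicular C2 axes and
  vertical mirror planes from the azimuths of the projected members and
  all pairwise bisectors.
* **Triply degenerate frames**: the polyhedral search — σ and C2
  (upgraded to C4 where valid) between equidistant point pairs (all
  pairs within an orbit are equidistant from the centre), vertex
  directions up to order 5, then *implied* elements: products of the
  validated operations (re-validated, since products of approximately
  valid operations drift), plus the tetrahedral special case where the
  C3 axes are generated from the diagonals of the three mutually
  perpendicular C2 axes.

Validation is mandatory and is the arbiter for every candidate: an
element's generator must map every atom within `tol_geom` (default
0.05 Å) of an atom of the same equivalence set, bijectively.  Validating
the generator suffices — powers of a valid permutation are valid.
Intersection across sets is implemented both as the literal list
matcher (`intersect_element_sets`, with C∞ ∩ Cn → Cn and gcd order
reconciliation) and, in the pipeline, as global validation of the
candidate union against every set, which is equivalent and also covers
singleton sets.  Molecule-level candidates along the molecular principal
axes cover the all-singleton corner (at most Cs there).  A known
limitation: a non-linear molecule whose only multi-atom orbits are
collinear pairs on a common axis relies on those molecule-level
candidates; mirrors not aligned with a molecular principal axis would be
missed in that corner, which cannot occur for orbit-generated input.

Detected labels follow the standard decision tree (linear → polyhedral
→ dihedral/cyclic), with the relaxation that a single perpendicular C2
or a single vertical mirror suffices since the remainder is implied and
regenerated.  The detected elements are then *symmetrised*: the exact
ideal element geometry of the label is aligned onto the detection — a
provisional primary/secondary axis match screened against the molecule,
refined by an orthogonal Procrustes fit over all matched axis pairs
(signs resolved per pair; axis bundles are centrosymmetric, so a proper
rotation always suffices).  Alignment residuals above 0.1 rad raise an
error.  All downstream operations are exact matrices conjugated by this
transform, which is why symmetrised geometries come out invariant to
1e-15 rather than to `tol_geom`.

## Point groups

Groups are generated in a canonical frame (principal axis z, first
perpendicular C2 along x, first σ_v through xz; polyhedral groups by
closure from generators, icosahedral orientation with C2 axes on the
coordinate axes).  The multiplication table is built by matrix matching;
conjugacy classes by `g r g⁻¹` over the table, then merged pairwise
with the inverse class.  The merge implements the real-character
convention: operations whose characters would be complex conjugates
(C₃ with C₃², the cubic-rotation pairs of T) share a class, matching a
basis of real spherical harmonics.  For ambivalent groups the merge is
a no-op.

Mirrors and perpendicular C2 axes are tagged horizontal / vertical /
dihedral relative to the principal axis: families alternate on the π/n
azimuth grid when n is even (the two ⊥C2 families of D₄h), collapse to
one when n is odd, and off-grid mirrors (bisecting the C2 axes, as in
Dnd) are dihedral.  Canonical operation order is identity, proper
rotations by descending order then ascending power, improper rotations,
mirrors (h, v, d), inversion — the order in which the regular-action
permutation cycles are reported.

Subgroups are enumerated exhaustively from the table: cyclic subgroups
from every operation's powers, then joins with cyclic subgroups iterated
to a fixed point.  Every subgroup of a finite O(3) group is cyclic,
dihedral or polyhedral and hence 2-generated — except the rank-3
elementary abelian D2h, which the fixed-point iteration still reaches.
Counts are cross-checked against closed forms where available (d(n) for
cyclic, σ(n)+d(n) for dihedral-type, 10/30/30/59 for T/Td/O/I); no
independent count was available for the centrosymmetric polyhedral
groups, so they are not pre-checked.  Subgroups are kept oriented — the
three distinct Cs of C3v are three subgroups — because partner-function
subduction needs a concrete mirror, not a conjugacy class.

## Character tables

Axial tables are *generated*, not stored.  Every operation of an axial
group factors through the plane perpendicular to the principal axis as
a 2-D rotation by φ or a reflection across azimuth β, times ε = ±1
along the axis.  One-dimensional irreps are the distinct ±1-valued
functions `χ = cos(j₀φ)` / `v·cos(2j₀(β−β₀))` times `(−1)^t` on
ε = −1 operations, with j₀ ∈ {0, N/2}, v, t ∈ {±1} and N the projected
rotation order; duplicates collapse automatically (S₆ keeps A labels,
C₄h gains B).  Two-dimensional irreps have χ(C^k) = 2cos(jk·2π/N)
(`e_character`), zero on flips and mirrors, and the ±(−1)^t factor
carrying the behaviour under σ_h into the improper operations.

Purely rotational projections (Cn, Cnh, S2n) have complex-conjugate
irrep pairs; these are emitted as merged real 2-D rows over the merged
classes, flagged `complex_pair`.  A merged row carries weight 2: the
dimension sum rule reads Σ dim²/w = |G|, row orthogonality
Σ|c|χχ' = w|G|δ, the reduction formula divides by w, and the trace
projector uses dim/(2|G|) — each identity is the mathematically forced
counterpart of merging, and `CharacterTable.validate()` checks them
all.  For real-type groups w = 1 and everything reduces to the
textbook statements.

Mulliken names are assigned by explicit rules: A/B from the character
under the principal rotation (the proper Cn when the group is
centrosymmetric, else the finest projected rotation — this names the B
of S₄ and D₂d by the S₂ₙ axis while keeping S₆ all-A), subscripts from
the first perpendicular C2 (or first σ_v), primes from σ_h, g/u from
inversion, E indices recovered from the finest-rotation character and
shown only when more than one E survives per parity.  D2/D2h use the
conventional B1/B2/B3 numbering by symmetry axis.  Polyhedral tables
(T, Td, Th, O, Oh, I, Ih) are static verified data keyed by
class-geometry invariants (proper/improper, angle, C4-axis sharing),
with the centrosymmetric groups formed as base ⊗ inversion.

Linear groups get a finite surrogate: C_(2ℓ)v or D_(2ℓ)h for a basis
with maximal angular momentum ℓ, with the vertical and dihedral C2/σ
operations merged into shared classes.  One-dimensional rows that stop
being class functions on the merged classes (the B pairs) merge into
2-D Λ = ℓ rows; their two constituent per-operation character rows are
retained so the partner components (the underlying B1/B2 subspaces) can
still be projected out.  Irreps are named Σ±/Π/Δ/… with g/u parity; the
surrogate splits every function up to ℓ exactly as the infinite group.

## Real spherical harmonics

Convention: real solid harmonics, m = −ℓ..ℓ, phase fixed so ℓ = 1 maps
to (y, z, x).  Rotation matrices come from the iterative order-raising
recursion (the U, V, W recurrence over the ℓ = 1 seed, with the
corrected sign convention in the V term); the implementation is verified
against an independent numerical oracle — real harmonics sampled on
random directions from the complex harmonics, the transformation solved
by least squares — to 1e-8 at every ℓ ≤ 6, rather than trusting any
single printed form of the recurrence.  Improper operations factor as
inversion ∘ rotation, with inversion acting on a shell as (−1)^ℓ.

Shell characters have closed forms — χ(Cₙ) = sin(θ|Y|/2)/sin(θ/2),
χ(Sₙ) = cos(θ|Y|/2)/cos(θ/2), χ(E) = |Y|, χ(i) = (−1)^ℓ|Y|, χ(σ) = 1,
with |Y| = 2ℓ+1 — so irrep spans need no matrices.  θ is taken from the
matrix trace (not the rationalised power/order) to keep generic angles
exact; the θ → 0 and θ → π singularities are resolved analytically.
Matrix traces equalling the closed-form characters for every operation
of every regression group is itself a consistency check of the two
independent routes, and is asserted in the test-suite.  Matrices are
cached per (ℓ, rotation).

## SALCs and partner functions

Per (equivalence set, ℓ) block, the group acts by
D^SY(R) = D^S(R) ⊗ D^Y(R); the trace projector extracts each irrep's
isotypic subspace, whose orthonormal span comes from a deterministic
pivoted LDLᵀ-style factorisation (largest diagonal first, ties by
index, signs fixed by the first significant coefficient) — the isotypic
subspace has infinitely many valid bases, so determinism is a contract,
not a nicety.  Degenerate irreps are split by subduction to the first
(smallest order, lowest canonical index) subgroup chain whose tables
contain no complex-pair irreps and whose subduced multiplicities are all
≤ 1: a single mirror subgroup for the E of C3v, an order-4 abelian
subgroup for 3- and 4-dimensional cubic/icosahedral irreps, and the
two-step chain through an order-10 dihedral subgroup then one of its C2
subgroups for the 5-dimensional icosahedral irreps.  Component 1 is
extracted from the chain projector; components k > 1 are images of
component 1 under the first group operation with a clean intrinsic
transfer (the transfer norm ‖P^γk D(R) v‖/‖v‖ equals |Γ(R)_{k1}|, an
irrep property independent of the block, so every (set, ℓ) block —
and every molecule in the same group — receives the same orientation).

Merged complex-pair irreps of purely rotational groups admit no real
splitting subgroup; their partner pairs come instead from the
antisymmetric part A = (D−Dᵀ)/2 of the principal generator restricted
to the isotypic space: each extracted vector v pairs with Av/|Av|,
spanning a generator-invariant 2-plane with a block-independent action.

The basis is assumed overlap-free; any contraction/overlap treatment
belongs downstream.  The full transfer-operator P^Γ_kl formalism is
intentionally not implemented — the trace projector plus subduction
reproduces its effect without needing explicit irrep matrices.

## Symmetrisation

*Geometry*: atomic displacements stacked into one (atom ⊗ cartesian)
vector are projected by the group average of D^S(R) ⊗ R.  The result is
exactly invariant (float precision); the discarded component is the
error indicator, reported both as the mass-weighted norm (Å·amu^½ — the
projector commutes with √mass scaling because orbits are equal-mass, so
the projection itself needs no weighting) and as a per-coordinate RMS
(Å), comparable directly to a coordinate noise level.  Projection that
brings two atoms within 1e-3 Å raises an inconsistent-group error.

*Wavefunctions*: each orbital's squared-norm fraction per irrep span is
reported; an orbital is assigned to its argmax irrep and projected
there.  Orbitals assigned to a degenerate irrep are taken in input
order as consecutive dim(Γ)-tuples (the layout degenerate SCF orbitals
arrive in); a common copy-vector is computed as the dominant eigenvector
of the accumulated component outer products — the "average component" —
and the tuple is replaced by that combination over the canonical
partner functions, so partner sets transform exactly into one another.
Outputs are Löwdin-orthonormalised within each irrep (order
independent).  An orbital whose largest fraction is ≤ `min_component`
(default 0.5, a strict majority) raises an error: there is a limit to
how symmetry-broken the input can be.

## Synthetic fixtures

The generator produces molecules by orbit expansion: every group
operation applied to seed positions, coincident images merged (merging
below |G| images requires an explicit special-position flag).  General
positions come from a fixed plastic-constant low-discrepancy sequence at
increasing radii (default 3 Å base), with distinct elements per orbit —
two orbits are required because a single Cn orbit is a regular polygon
with strictly higher symmetry.  A quasi-random seed set can still land
within `tol_geom` of a *supergroup* (two rings whose azimuth offset
almost matches a mirror grid); a tolerance-honouring detector then
correctly reports the higher group, which makes a wrong fixture rather
than a wrong detector.  The generator therefore verifies that the ideal
orbit detects as exactly the requested label and advances the
deterministic sequence until it does; what the regression sweep then
demonstrates is that *robustly general* orbits of every family
(n = 2..12, all polyhedral groups, D₁₃d/D₄₇d nanotubes) are labelled
exactly.  Noise is isotropic Gaussian with a fixed seed.  The fixtures
emulate geometric symmetry only — no chemically meaningful bond lengths,
no vibrational correlations in the noise — so passing tests speak to
the symmetry machinery, not to behaviour on real force-field output.

Synthetic orbital sets mix SALC rows with a declared squared-norm
fraction of cross-irrep contamination (partner tuples adjacent), with
ground-truth assignments recorded for recovery tests.

## Tolerances (defaults)

| parameter | default | meaning |
|---|---|---|
| `tol_geom` | 0.05 Å | element validation: max atom mismatch |
| `rel_tol` | 1e-3 | equivalence clustering, relative |
| `deg_tol` | 0.02 | relative moment-degeneracy in detection frames |
| frame `deg_tol` | 1e-4 | moment degeneracy for exact frame classification |
| `lin_tol` | 1e-6 (`(tol/4)²` in detection) | linearity threshold |
| alignment `max_residual` | 0.1 rad | detected-vs-ideal axis mismatch |
| `min_component` | 0.5 | orbital majority-irrep threshold |
| subgroup cap | 240 | largest group enumerated |

Problem sizes in the shipped tests: orbit molecules up to 240 atoms
(two Ih orbits), nanotubes up to 188 atoms (D₄₇d), SALC bases up to
ℓ = 3 on 21 atoms (336 functions); these sizes exercise every code path
while keeping the default suite fast.
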