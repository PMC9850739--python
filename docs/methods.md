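# Methods

This note documents the models, conventions, and numerical choices behind
`pesscan`, and what its synthetic study systems do and do not demonstrate.

## Scan data model and units

A scan is an ordered set of points along one internal coordinate.  Canonical
units are Å for distances, degrees for angles/dihedrals, Hartree for stored
SCF energies, and kJ/mol for everything the fitting layer touches.  The
single conversion constant, 2625.499639479826 kJ/mol per Hartree, is pinned
bit-exactly in `pesscan.model` and used nowhere else.  Atom indices are
1-based wherever they face users or input files (quantum-chemistry inputs
are 1-based); 0-based indices appear only as internal list positions.

Dihedrals are signed, in (−180°, 180°], with the IUPAC convention
(clockwise rotation of the far bond positive when sighting along the
central bond), computed as atan2((n₁×n₂)·b̂₂, n₁·n₂).  Note the signed
torsion is *invariant* under reversing the atom order (DCBA = ABCD) and
changes sign under reflection; both identities are property-tested.

Scan points are re-sorted ascending by coordinate value at assembly, with
the original file order kept as a provenance field (`source_order`).
Duplicate coordinate values (|Δ| < 10⁻⁶ in coordinate units) are collapsed
keeping the lowest SCF energy, the conservative choice for relaxed scans
where a lower energy at the same constraint means a better-optimized point.
Within one scan, duplicates are forbidden outright by validation, so a
rigid and a relaxed pass over the same grid belong in two scan instances.

## Log dialect

The parser consumes a minimal, documented text dialect replicating the
anchor strings of Gaussian-style output: orientation tables, `SCF Done:`
lines, `Optimization completed./stopped.` markers, and ModRedundant-style
scan declarations (`B i j S n step`, `A i j k S n step`, `D i j k l S n
step`).  Relaxed scans yield one step per optimization marker — the last
SCF energy and the last preceding geometry block, preferring *Input
orientation* because it preserves the input atom order; rigid and
single-point logs yield one step per SCF line.  Unconverged steps are
retained with `converged=False` and excluded from assembly, so provenance
survives without corrupting profiles.  Energies are stored exactly as
printed (decimal text) so parse → assemble → serialize round trips are
bit-exact.  Real logs using these anchors should parse, but only the
documented dialect is guaranteed.

## RDF mapping

Scans map to triples under a compact vocabulary mirroring the published
class and property names for PES-scan semantics; species and calculation
details use minimal surrogate terms, declared (and overridable term-by-term)
in `VocabularyMap` rather than asserted as authoritative upstream IRIs.
Quantities use the value+unit node pattern.  Numeric literals are
`xsd:decimal` with exponent-free, shortest-round-trip lexical forms:
`xsd:double` was rejected because Turtle serializers print it in rounded
scientific notation, destroying bit-exact reloads.  Multiple fitting
records per scan are grouped under per-record nodes (linked by an extension
term `hasFitting`) because flat method/source/parameter properties on the
scan node cannot be disambiguated once a second record arrives; the fitting
node IRI is a content hash, which makes `attach_fitting` idempotent for
identical records.

## Force-field evaluation

State topologies are always explicit (automatic atom typing is out of
scope; the user-supplied-topology path is the supported one).  Functional
forms are pinned to one convention: ½k(r−r₀)² bonds, Dₑ(1−e^{−a(r−rₑ)})²
Morse bonds, ½k_θ(θ−θ₀)² angles, (Vₙ/2)(1+cos(nφ−γ)) torsions, 12-6
Lennard-Jones with Lorentz–Berthelot mixing, and Coulomb with
f = 138.935458 kJ·mol⁻¹·Å·e⁻².  Nonbonded exclusions follow the common
OPLS-like policy — 1-2 and 1-3 excluded, 1-4 scaled by 0.5 for both LJ and
Coulomb, both factors configurable.  No cutoffs and no periodic boundary
conditions: the targets are gas-phase clusters along a scan, where the
exact lattice conventions of an MD engine are irrelevant.

## EVB coupling calibration

States are identified on the reference profile by the rule: the reactant is
the local minimum of lowest energy; for bond-distance scans with exactly
one local minimum the product is the maximum-distance point (the dissociated
fragments), otherwise the second-lowest local minimum.  Angle and dihedral
scans have no maximum-distance fallback and require either two minima or
explicit anchors.

Each state is anchored to the reference at its own state point
(shift = Eref − E at the anchor), generalizing the usual zero-of-energy
convention.  Anchored shifts are deliberately only the default: wherever
the coupling is nonzero it depresses the reference *below* the diagonal
state energies at the anchors, so anchored shifts carry an O(A²/ΔE) bias
and exact recovery of an embedded coupling requires co-optimizing the
shifts (`optimize_shifts=True`), which the recovery studies use.

The coupling is constant or single-Gaussian — both standard EVB practice;
the functional form is this package's declared choice, not an attribution.
Calibration minimizes Σᵢ(E_EVB,i − Eref,i)² with a deterministic pipeline:
initialization from pointwise-coupling statistics (h₁₂ = √((E₁−Eref)(E₂−Eref))
inverted from the eigenvalue relation; median for the constant model, peak
height/location and second moment for the Gaussian), bounded Nelder–Mead
descent (iteration budget 10⁴, objective tolerance 10⁻¹² (kJ/mol)²), then a
bounded trust-region least-squares polish.  The polish is derivative-based
but deterministic; it is kept because the simplex step alone stalls one or
two digits short of the 10⁻⁶ recovery contract.  Non-convergence is
reported via `converged=False`, never raised.  A = 0 is allowed (bounds
[0, ∞)); h₁₂ = 0 returns min(E₁, E₂) bit-exactly.

## Morse fitting

V(r) = Dₑ(1−e^{−a(r−rₑ)})² + V₀ is fitted by bounded least squares with a
deterministic initial guess: rₑ from the argmin, V₀ from the minimum, Dₑ
from the right-tail plateau, and a from √(k/2Dₑ) with k the curvature of a
parabola through the three points around the minimum (valid on uneven
grids).  Profiles whose minimum sits on the grid boundary, or with no right
tail above the minimum, raise a no-well error rather than extrapolating.

## Synthetic study systems

The two-state generator is the exact forward model of the calibration
problem: Eref = E_EVB(E₁+s₁, E₂+s₂, H₁₂(r)) plus optional seeded Gaussian
noise, with the ground truth returned alongside.  The default system uses
two harmonic diatomic states (k = 900 and 350 kJ/mol/Å², wells at 1.5 and
3.0 Å — a stiff covalent-bond-like state dissociating toward a soft,
40 kJ/mol endo-ergic product state), a 40-point grid on [1.2, 4.0] Å, and
A = 25 kJ/mol, values a practitioner would call representative of a
single-bond scission scan.  The worked-example fixture is a 9-atom
ethanol-like cluster whose C–C bond scan starts at exactly 1.51 Å with
Morse-shaped energies; it is synthetic throughout (labelled so) and mimics
the shape, not the values, of any real calculation.

What passing these studies shows: the calibration machinery inverts its own
forward model exactly, the parser and graph mappings are lossless on
dialect-conformant data, and the estimator is unbiased under additive
Gaussian noise.  What it does not show: agreement with real DFT reference
surfaces, real force-field libraries, or real Gaussian logs outside the
documented anchors — those require external data and engines this package
does not bundle.

## Noise and identifiability

Under additive noise the constant-coupling estimate is unbiased, but its
precision is governed by where the coupling is observable: the sensitivity
∂E_EVB/∂A = 2A/√(Δ² + 4A²) is ≈1 only near the state-crossing seam
(Δ = E₁−E₂ ≈ 0) and decays like A/|Δ| elsewhere.  For the default system at
σ = 1 kJ/mol the Cramér–Rao bound is sd(Â) ≈ 0.84 kJ/mol with jointly
estimated shifts (0.63 even with shifts known); the calibrator achieves
≈0.98, i.e. it is close to efficient, and no estimator can do better than
the bound under these conditions.  Noise-robustness expectations should
therefore be framed against the seam-limited information content, not
against a √n law over the full grid.

## Problem sizes

The bundled studies use 40-point coupling grids, 60-point Morse profiles,
100 noise seeds, 10⁴ random Hamiltonians/triples for the algebraic
identities, and 1000 random profiles for the state-rule check — sizes at
which every identity is sharp and the full suite plus the acceptance script
run in well under a minute on one CPU.

## Known limitations

One scan coordinate per scan (multidimensional surfaces out of scope);
two states only (no multi-state EVB); no coupling dependence on environment;
no parameter uncertainties beyond residual diagnostics; no MD integration or
forces; topologies must be supplied explicitly; the log parser guarantees
only its documented dialect.
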