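# pesscan

Tools for one-dimensional potential-energy-surface (PES) scans: parse
quantum-chemistry scan logs, store and query scans as RDF knowledge graphs,
and calibrate reactive force fields against them with the empirical valence
bond (EVB) method.

## The problem

A 1D PES scan samples the electronic energy of a molecular system along one
internal coordinate — a bond distance, plane angle, or dihedral — and is the
workhorse reference for parametrizing reactive force fields, computing
bond-scission rate coefficients, and treating hindered rotors.  Scan data is
usually locked inside program-specific log files.  `pesscan` addresses two
needs of computational chemists working with such data:

1. **Scans as linked data.**  A scan is modelled semantically: a
   `PotentialEnergySurfaceScan` linked to species (by IRI and InChI), to one
   scan coordinate defined by atom references, and to per-point calculation
   records (converged SCF energy in Hartree, geometry in Å, level of
   theory).  Scans serialize to/from Turtle and support the two canonical
   query patterns: *find scans on a species by InChI* and *retrieve the
   energy profile of a scan*.

2. **Reactive force fields without reactive force fields.**  The EVB method
   joins two ordinary (non-reactive) classical force fields — one per
   chemical state — into a reactive surface.  With state energies E₁(r),
   E₂(r) on the diagonal and a coupling H₁₂(r) off the diagonal of a 2×2
   Hamiltonian, the reactive ground state is the lower eigenvalue

   E_EVB(r) = ½(E₁+E₂) − ½√((E₁−E₂)² + 4H₁₂²).

   `pesscan` identifies the reactant/product states on the reference
   profile (local minima; the maximum-distance point for single-well bond
   scans), anchors the state energies, and calibrates H₁₂ — a constant A or
   a Gaussian A·exp(−(r−r₀)²/(2w²)) — by least squares so E_EVB reproduces
   the reference energies, reporting per-point residuals and the maximum
   absolute residual.  A Morse fitter V(r) = Dₑ(1−e^{−a(r−rₑ)})² + V₀
   covers the classic dissociation-curve case.

Fitting follows the model/results idiom: build `EVBCouplingModel` (or
`MorseModel`) from data, call `fit()`, read estimates and diagnostics off
the result.

## Worked example

Generate a synthetic two-state system with a known constant coupling of
25 kJ/mol embedded via the exact EVB forward model, then recover it:

```python
from pesscan import synth
from pesscan.fitting import calibrate

data, truth = synth.make_two_state_system(synth.default_two_state_spec())
result = calibrate(data, "constant", optimize_shifts=True)
print(result.summary())
```

```
Two-state EVB coupling calibration
==================================
coupling model : constant
  A           :  25
  s1 (shift)  : -2.3183633e-15 kJ/mol
  s2 (shift)  :  40 kJ/mol
anchors (reactant, product): (4, 25)
objective (sum sq. residual): 7.27014e-27 (kJ/mol)^2
max |residual|: 5.68434e-14 kJ/mol
converged     : True
n points      : 40
```

The calibration recovers the embedded coupling A = 25 kJ/mol and the
state-2 energy offset (40 kJ/mol, the reaction endo-ergicity built into the
fixture) to machine precision; the maximum residual of ~6·10⁻¹⁴ kJ/mol says
the EVB surface reproduces the reference exactly, as it must on noiseless
forward-generated data.  The anchors are the grid indices picked as the
reactant state (the deep well at index 4) and product state (the shallow
well at index 25).

The command-line surface mirrors the same pipeline for files on disk:

```sh
pesscan gen-fixtures fixtures --seed 1        # synthetic logs + graph + tables
pesscan parse --config parse.yaml             # logs -> scan.ttl + validation report
pesscan query fixtures/ethanol_scan.ttl energies   # coordinate,unit,energy table
pesscan fit --config fit.yaml                 # calibrate + attach fitting record
```

`pesscan query ... energies` on the bundled worked-example scan prints a
table whose first row starts at `1.51,angstrom,…` — the first point of the
synthetic carbon–carbon bond scan.

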