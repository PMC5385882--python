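# Methods

This note records the model as implemented, the provenance of every
parameter, the numerical choices, and what the synthetic fixtures do and
do not establish about real RNA.

## Representation

Five beads per nucleotide: phosphate (P, anchored at the P atom), sugar
(S, at C4'), and three beads in the base plane.  The base-bead anchors
and the nine-type assignment are *data* (`data/mapping.tsv`), not code,
because they are a modelling convention rather than a derivable fact.
The shipped convention uses a ring bead shared within each pyrimidine or
purine class (RA at C8, RY at C6), a shared Watson–Crick imino bead (NI
at purine N1 / pyrimidine N3) and one residue-specific edge bead (N6,
O6, N4, O4).  This yields 9 types (P, S + 7 base types), places all
three base anchors in the base plane, and makes the canonical pairing
contacts expressible as type pairs: NI–NI, N6–O4 (A–U), O6–N4 (G–C).
Alternative tables can be loaded without code changes.

5'-terminal phosphates: present in sequence-built structures, omitted
(and recorded in `meta['missing_5p']`) when the source PDB lacks them.
Bead masses are the approximate summed masses of the chemical moiety
each bead represents, so total molecular mass is roughly conserved for
dynamics; they are inertial bookkeeping only and do not affect
configurational averages.

## Energy terms and conventions

* Harmonic bonds and angles use `k (x − x₀)²` with **no ½ prefactor**
  throughout the package (including umbrella restraints).  Parameter
  files state k in kcal/mol/Å² or kcal/mol/rad² under this convention.
* Torsions: `Σ_{n=1..3} kₙ [1 + cos(nφ − δₙ)]`, φ by the standard
  atan2 construction with the IUPAC sign convention.  Torsions whose
  inner three beads become collinear (undefined dihedral) contribute
  zero with a warning.
* Effective vdW: `U(r) = ε (e^{−2γ(r−σ)/σ} − 2 e^{−γ(r−σ)/σ})`, a
  Morse-type form chosen because it satisfies the term's defining
  contract — U(σ) = −ε, U′(σ) = 0, U(∞) = 0, γ controls the slope of
  the short-range wall — while keeping the wall finite and much softer
  than r⁻¹², which is the property that motivates a three-parameter
  effective potential in the first place.  Combining rules for unlike
  types: geometric mean for ε and γ, arithmetic mean for σ (symmetric,
  identity on like pairs).  Truncated at 12 Å with an energy shift.
* Hydrogen bonds: pair energy `−ε_hb S(r) R(r) f(cos θᵢ) f(cos θⱼ)` with
  the 10-12 radial profile `R(r) = 6(σ_eq/r)¹⁰ − 5(σ_eq/r)¹²`
  (maximum 1 at σ_eq = 2.9 Å), `f(c) = max(c, 0)²`, and a quintic
  switch S(r) from 4.5 Å to the 6 Å cutoff so energy *and* gradient
  vanish exactly at the cutoff.  θᵢ is the angle between base i's edge
  vector (base-bead-triangle centroid → edge bead) and the interatomic
  direction; ideal pairing has both cosines at 1, stacked geometry has
  them near 0, so the term separates pairing from stacking.  ε_hb,max =
  2.0 kcal/mol; eligible type pairs (canonical and noncanonical edge
  combinations) are listed in the parameter file.  The clamp `max(c,0)`
  keeps f and f′ continuous at the node, so the analytic gradient is
  exact everywhere.
* Electrostatics: `C qᵢqⱼ e^{−r/ξ}/(D r)`, C = 332.0637 kcal·Å/mol/e²,
  phosphate charge −1 e, D = 25, ξ = 10 Å (≈0.1 M monovalent salt;
  configurable — the physical salt dependence of ξ is not modelled).
  Truncated at 4ξ with an energy shift.
* Exclusions: 1-2 and 1-3 pairs are excluded from both non-bonded
  terms; 1-4 pairs are fully included (their geometry is governed by
  the torsion terms).

## Parameter provenance

Printed, fixed constants: ε_hb,max = 2.0 kcal/mol, σ_hb,eq = 2.9 Å,
H-bond cutoff 6 Å, dielectric D = 25, the annealing ladder
(298, 400, 1000, 900, 800, 700, 600, 500, 400, 298 K × 5 ns, 1 fs
step, snapshots every 10 ps), pulling conventions (1 kcal/mol/Å²
spring, 1 Å window spacing from 5.5 Å to the n×5.9 Å contour, 4 fs
step), the 0.1 kcal/mol/Å unfolded-state force threshold, the 4 Å force
smoothing window, V_ref = 1660 Å³ and T = 298 K.

Everything else in `data/default.ff` is this package's own
parameterization, annotated in-file by provenance class: equilibrium
bond lengths, angles and torsion phases were measured once from the
ideal A-form fixture lattice (so the lattice is near — not exactly at —
the force-field minimum); stiffnesses and vdW (ε, σ, γ) triples are
physically reasonable assigned values.  Because bonded terms are keyed
by bead-type tuples, geometrically distinct terms that share a type key
(e.g. P–S–B1 within a residue vs B1–S–P across a junction) are averaged;
this leaves a residual bonded strain of a few kcal/mol on the ideal
lattice and shifts the relaxed duplex ~1.7 Å RMSD from it.  The
machinery to refit every term from structure statistics
(`statpot.fit_bonded`, `statpot.fit_vdw_eff`) is part of the package;
the shipped numbers are a starting point, not a claim of transferable
accuracy.

## Statistical potentials

RDF normalizations: 3-D divides unordered pair counts by
`n_pairs · 4πr²Δr / V`; 1-D divides by `n_pairs · 2Δr / L` (the 1-D
"shell" at distance r is the two points ±r).  When no reference
volume/length is supplied, g is self-normalized so its mean over the
outer 20 % of the r range is 1 — the operational g→1 asymptote, since a
database of structures has no well-defined V or L.  Boltzmann inversion
uses −kT ln g at 298 K, zero-count bins are marked invalid rather than
imputed, and the curve is shifted so its minimum is exactly 0.  The
vdW fit therefore includes a free additive offset alongside (ε, σ, γ);
multi-start least squares over γ ∈ {5, 10, 20} guards against the
shallow-γ local minima.  Defaults: 0.1 Å bins, r_max 20 Å.

## Dynamics

Velocity-Verlet integration in Å/ps/amu/kcal·mol⁻¹ units; the
thermostat is the BAOAB splitting of Langevin dynamics with friction
1 ps⁻¹ (robust at the 1000 K annealing stages, accurate configurational
sampling at large steps).  Initial velocities are Maxwell–Boltzmann at
the stage temperature; every stochastic entry point takes a seed and is
bit-reproducible.  No constraints are used; a non-finite coordinate
aborts the run with the step index.  Minimization is L-BFGS with the
analytic gradient, converged at RMS gradient ≤ 0.01 kcal/mol/Å by
default; "minimized" landscape snapshots use a looser 0.05–0.3
tolerance because landscape shape, not micro-convergence, is the
object.  Annealing schedules scale *durations and snapshot interval
proportionally* under `scaled(f)`, conserving the snapshot count.

## Free energies

The reaction coordinate is the distance between terminal sugar beads
(for duplexes: the two strands' sugars at the pulled end; the far-end
pair is held by a 1 kcal/mol/Å² restraint at its native separation, and
a weak flat-bottom intra-strand restraint — default 0.1 kcal/mol/Å²
engaging below half the native strand extension — discourages
long-lived hairpin-like intra-strand states).  Windows run serially,
each starting from the previous window's final frame.

WHAM iterates the standard coupled equations on a histogram grid
(default 0.2 Å bins) until window shifts change by < 10⁻⁶ kcal/mol;
adjacent windows whose sample ranges do not overlap raise an error
naming the gap.  Uncertainties use a moving-block bootstrap with block
length set to the integrated autocorrelation time of each window's time
series (MD samples are correlated; i.i.d. resampling would
underestimate errors); n_boot = 100 by default, and n_boot < 2 is
flagged insufficient.

ΔG convention: Δω is re-referenced to zero at the unfolded state
(the last grid point where the 4 Å-smoothed force is below
0.1 kcal/mol/Å before the terminal over-stretched rise), and

    ΔG = −kT ln[(1/V_ref) ∫_{r ≤ r_unfolded} e^{−Δω(r)/kT} J(r) dr].

The volume element J(r) defaults to the spherical shell 4πr², which
makes the 1660 Å³ standard-state volume dimensionally consistent with a
scalar end-to-end coordinate; J = 1 Å² is available behind the
`jacobian="unit"` flag for comparison with line-integral conventions.
ΔG is invariant to any additive constant on Δω (the reference shift
cancels it) and monotone in pointwise well depth.

`setup_windows` follows the n×5.9 Å contour formula exactly and accepts
an explicit `max_center` override for protocols whose printed window
maxima differ from the formula (duplexes, and some hairpin lengths, are
published with maxima a few Å beyond it).

## Synthetic fixtures and what tests show

The ideal-helix generator places beads on a parametric A-form lattice
(rise 2.8 Å/bp, twist 32.7°/bp, sugar radius 9.2 Å, phosphate radius
10.4 Å) with paired imino beads exactly 2.9 Å apart and edge vectors
exactly anti-aligned; antisense strands are generated by a proper
rotation so bonded geometry, including torsion signs, matches the sense
strand.  Hairpin loops ride a circular arc with per-residue geometry
copied rigidly from the helix template.  The ring and edge beads sit at
staggered radii (4.6 / 3.4 Å) so that consecutive stacked beads do not
coincide vertically.

These fixtures are idealized: bases are perpendicular to the helix axis
(no inclination or propeller twist), loops are geometric arcs, and no
structural disorder exists.  Passing tests therefore establish that the
machinery — mapping, energies, gradients, integrators, WHAM, ΔG — is
correct on exactly constructed inputs with known answers; they do not
establish thermodynamic accuracy for real RNA, which would require
refitting the statistical potentials against an experimental structure
corpus and microsecond-per-window sampling.  Scaled-down test runs
(picosecond annealing stages, thousands of MD steps per umbrella
window, 5-window pulls) exercise the identical code paths as
production-scale protocols; the full published-scale protocols are the
package defaults.

The exact 1-D Boltzmann sampler (inverse CDF on an 8192-point grid) is
the oracle for the PMF and WHAM tests: recovered profiles must match
the generating potential to 0.1 and 0.2 kcal/mol RMS respectively.

## Known limitations

* The shipped force-field numbers are assigned, not fitted to an
  experimental corpus; quantitative folding free energies from
  simulation with this file are not expected to match experiment.
* Type-keyed bonded parameters cannot distinguish geometrically
  distinct terms sharing a type signature (see above).
* Implicit solvent only; no explicit ions, no salt-dependence of ξ
  beyond manual configuration; no modified nucleotides; no mmCIF input;
  no all-atom back-mapping refinement.
* The hydrogen-bond directional definition (centroid → edge bead)
  is one reasonable realization of base-edge alignment; others (e.g.
  ring-normal based) would differ away from the ideal geometry while
  satisfying the same contracts at it.
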