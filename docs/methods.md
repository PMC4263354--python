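# Methods

## Elastic model and conventions

The bilayer is treated in the Monge gauge through the leaflet
hydrophobic half-thickness deviation *u*(x, y) (nm), with the quadratic
energy functional

    G[u] = ∫ dx dy [ (K_b/2)(∇²u)² + (K_t/2)(u/a)² + (τ/2)(∇u)² + τ u/a ].

Conventions, fixed once and used everywhere:

* *u* is a per-leaflet (half-thickness) quantity; the functional is the
  energy of the whole bilayer.  K_t is therefore of the order of the
  bilayer area-stretch modulus, and K_b the bilayer bending modulus.
* Energies in k_BT, lengths in nm, tension in k_BT/nm².
* All reported energies are measured relative to the flat membrane at
  the same tension.  Tension thins the bilayer to u_eq = −τa/K_t, at
  which the linear coupling τu/a is stationary; relative to that state
  the energy is a pure quadratic form in h = u − u_eq and a protein of
  half-thickness w imposes the *effective* mismatch (w − a) + τa/K_t on
  its boundary.  Consequences: (i) at zero tension, zero mismatch means
  zero energy identically; (ii) at positive mismatch every energy grows
  with tension, both through the effective mismatch and through the
  (τ/2)(∇u)² term.

Exponential solutions require K_b ν² − τν + K_t/a² = 0.  Below the
degeneracy tension τ_c = 2√(K_b K_t)/a (≈ 50 k_BT/nm² for the defaults —
far above bilayer rupture) the roots ν± are complex conjugates, giving
exponentially damped oscillatory profiles (the thickness "overshoot"
that produces the intermediate repulsive regime of the pair potential).
Exactly repeated roots are flagged, and the single-inclusion closed form
switches to the confluent limiting family ∂K_0(√ν r)/∂ν; the
multi-inclusion collocation solver refuses this measure-zero case
rather than perturbing parameters.

### Boundary conditions at the protein edge

The field equals the effective mismatch on the inclusion boundary.  For
the second condition of the fourth-order problem the package implements
both a clamped (zero) boundary slope and the energy-minimising natural
condition (∇²u = 0), switchable via `slope_bc`.  **The default is the
clamped slope**, the standard choice in hydrophobic-mismatch
calculations for gramicidin and mechanosensitive channels: the lipids
adjacent to the protein wall are taken to sit flush against a rigid
hydrophobic surface.  The free-slope variant yields interactions roughly
an order of magnitude weaker and is retained for sensitivity analysis.

## Parameters (E. coli/Trg preset)

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| bending modulus | K_b | 20 | k_BT | typical measured bilayer value |
| thickness stiffness | K_t | 60 | k_BT/nm² | typical measured (stretch-modulus scale) |
| tension | τ | 0 | k_BT/nm² | reference state; scans go to rupture scale ~2 |
| monolayer hydrophobic thickness | a | 1.4 | nm | E. coli inner-membrane hydrophobic core ≈ 2.8 nm |
| trimer hydrophobic half-thickness | w | 1.8 | nm | Trg hydrophobic thickness ≈ 3.6 nm |
| trimer mean radius | R | 3.1 | nm | transmembrane cross-section of a trimer-of-dimers |
| three-fold amplitude | ε | 0.2 | — | "weakly perturbed" cylinder; see sensitivity below |
| steric clearance | — | 0.8 | nm | finite lipid/trimer size (minimum edge-to-edge gap) |
| observed face-on spacing | — | 12/√3 ≈ 6.93 | nm | conserved 12 nm honeycomb lattice constant |
| piston shift | δ | 0.16 | nm | helix displacement between signaling states |
| lipid site area | — | 0.65 | nm² | per-lipid area, one leaflet (lattice-gas site) |
| cell geometry | — | 1 µm × 3 µm rod | — | hemispherical poles; pole mean curvature 2× midcell |
| cone contact angle | α | 0.1 | rad | small tilt of transmembrane helices; order-of-magnitude choice |

The preset places the decay length at 1.27 nm and the mismatch at
+0.4 nm (trimer thicker than bilayer, so interactions strengthen with
tension).  With these values the model's calibration anchors hold
simultaneously: face-on binding at the 0.8 nm steric minimum exceeds
15 k_BT, the tip-on/face-on difference exceeds 10 k_BT, and the
nucleation threshold lands at a few tens of trimers per cell.  The
isolated-trimer deformation energy implied by this parameter set is
several tens of k_BT; all pair and lattice quantities are differences
of such energies.

## Geometry

Trimer cross-section r(θ) = R[1 + ε cos 3(θ − ω)]; "tips" are the three
maxima, "faces" the minima between them.  With the bond along +x,
tip-on is (ω₁, ω₂) = (0, π/3) and face-on (π/3, 0); both are
mirror-symmetric about the bond axis.  Steric minima solve
gap(d) = clearance by bracketed root finding on a signed gap function
(dense boundary sampling; negative on overlap, so overlapping
configurations are detected robustly).  With ε = 0.2 the face-on pair
reaches d = 6.17 nm and the tip-on pair 8.24 nm at 0.8 nm clearance —
the observed 6.93 nm face-on spacing sits just outside face-on contact.

The gateway family counter-rotates the two trimers, ω₁ = γ and
ω₂ = π/3 − γ, preserving the perpendicular-bisector mirror symmetry,
each configuration at its own steric-minimum distance.

Lattices: hexagonal (six neighbours, uniform orientation) and the two
honeycombs (three neighbours, two-sublattice rule making every bond
face-on or tip-on).  **Hexagonal orientation convention:** the uniform
orientation is ω = π/6, placing tips midway between bond directions so
that all six bonds are equivalent and mirror-symmetric.  This is a real
modelling choice: if instead tips point along three of the bonds
(ω = 0), those bonds become tip-to-face contacts, the hexagonal steric
floor moves inward, and the hexagonal lattice can outcompete the
face-on honeycomb.  The architecture ranking reported by the package is
conditional on the symmetric convention; the alternative is available
through the API (`PairConfiguration(d, −ω, −ω)` bonds).

## Numerical methods

**Series solver.**  The field is expanded in decaying cylindrical
harmonics K_n(√ν± ρ_i)e^{inθ_i} about each inclusion (real/imaginary
parts of one family in the conjugate-root regime; both real families
above τ_c).  Boundary conditions are imposed on the *exact* perturbed
boundary curves by least-squares collocation (midpoint nodes, 8 points
per retained order, value rows and slope/natural rows balanced by the
characteristic wavenumber, column equilibration before `lstsq`).
Energies come from exact boundary-term integrals of the quadratic form,
evaluated by periodic trapezoidal quadrature — spectrally accurate for
solutions of the field equation.  Interaction energies always subtract
isolated-inclusion energies computed *at the same truncation order*, so
G_int → 0 exactly as the inclusions decouple.

Truncation: default N = 12 harmonics per inclusion per family.  At
contact separations the energy drifts by ~1 k_BT between N = 8 and 10
and settles to ~0.1 k_BT by N = 12–14, so the optional convergence
check compares N with N − 2 against a configurable tolerance (default
0.25 k_BT) and raises with diagnostics on failure.

**Grid oracle.**  An independent finite-difference relaxation: 5-point
Laplacians and centred gradients on a regular grid, field pinned to the
effective mismatch on rasterised inclusion interiors and to zero on the
outer frame (domain padding 6 decay lengths), energy assembled as a
sum of squares (hence SPD) and minimised by a sparse direct solve.
Including the Laplacian stencils centred on interior nodes enforces the
clamped slope in the continuum limit; restricting them to membrane
nodes gives the natural condition.  Convergence is first order in the
spacing because of the staircase boundary; `richardson=True`
extrapolates from two spacings.  For interaction energies the oracle's
noise floor scales with the isolated energies (G_int is a small
difference of three large numbers), so equivalence tests use the
tolerance 0.12·|G| + 0.005·(E₁+E₂) + 0.4 k_BT with spacing =
decay length/10 — a tolerance model derived from refinement studies,
not from any target value.

**Quadrature.**  `deformation_energy` integrates the energy density of
any evaluatable field with central differences, excluding a two-cell
rim around inclusion interiors; the rim makes the error linear in the
spacing, and `refine=True` removes it by two-spacing extrapolation
(≤0.5% against the closed forms at 0.02 nm spacing).  A boundary-flux
check rejects domains on which the field has not decayed.

## Signaling

Signaling states differ by δ = 0.16 nm in full hydrophobic thickness
(half-thicknesses w ± δ/4), uniform along the circumference; the on
state is the thicker one by default (`thicker="off"` flips the sign,
which mirrors all transition energies without changing shifts).  The
cooperativity calculation is strictly pairwise: the on→off transition
energy of a central trimer with n of its three face-on neighbours off
is affine in n by construction, with per-neighbour shift
−[G(on,on) + G(off,off) − 2G(on,off)].  Because both states have
positive mismatch, the mixed pair lies *between* the two matched pairs
(attraction scales with the mismatch product); cooperativity arises
from the convexity combination above, not from the mixed pair being
absolutely repulsive.  The isolated-trimer membrane term is large and
must be compensated by internal protein contributions — receptors
operate near zero total transition energy; the package asserts only the
membrane term.

## Mesoscale estimates

**Nucleation.**  The critical concentration is a lattice-gas
condensation threshold: x_c = exp(−|E_b|/k_BT), with E_b the face-on
bond energy evaluated at the observed lattice separation (the condensed
phase that actually forms, its spacing set by the CheA/CheW rings) and
x_c a trimer-per-lipid-site mole fraction (site area 0.65 nm²),
converted to a count with the default cell membrane area.  This is the
package's reconstruction of a standard dilute-phase estimate; it is
exponentially sensitive to E_b and conventions, and is reported as an
order-of-magnitude quantity.  Deeper binding strictly lowers the
count, and the count depends only on the binding energy, never on an
overall energy offset.

**Polar localization.**  A conical trimer (midplane contact angle α)
on a background of mean curvature H carries a slope mismatch
s = α − HR.  Two standard formulations bracket the midplane energy:
(a) local curvature frustration over the footprint, 2πκs², and (b) a
cone solution with logarithmic regularisation, πκs² ln(ℓ/R), with ℓ the
tension length √(κ/τ) capped by the cell radius.  Their spread defines
the (lower, upper) interval; the poles-vs-midcell difference per trimer
is the interval difference and the N-trimer localization energy is N
times it — linear by construction.  A flat inclusion (α = 0) on a flat
membrane costs exactly zero; on the cell's curvature it costs a
negligible fraction of k_BT.  The far-field curvature-mediated pair
repulsion is estimated as 4πκ(α₁² + α₂²)(R/d)⁴ and is more than an
order of magnitude below the thickness-mediated interactions at the
same separations.

## Randomized verification cases

The case generator draws membrane and shape parameters bracketing the
preset (monolayer thickness 1.2–1.7 nm, mismatch of either sign up to
0.5 nm, tension 0–2 k_BT/nm², ε 0–0.3, R 2.6–3.6 nm), arbitrary
orientations, and distances from the steric minimum to +4 nm, all
sterically valid by construction.  These cases exercise the *solvers*
across the physical regime; they emulate parameter uncertainty, not
real membranes.  Passing the equivalence suite shows that the series
and grid methods solve the same continuum model — it says nothing about
lipid tilt, protein flexibility, thermal shape fluctuations, leaflet
asymmetry, or specific lipid–protein chemistry, none of which are in
the model.

## Known limitations

* Linear (small-gradient) elasticity with rigid inclusions; no lipid
  tilt degrees of freedom, no bilayer asymmetry, no fluctuation
  (Casimir-type) forces.
* Pairwise additivity for lattices: many-body corrections to
  overlapping deformation fields are neglected, consistent with the
  shell-truncation checks but unvalidated at very high density.
* The trimer cross-section is a single-harmonic perturbed cylinder; the
  architecture ranking is sensitive to the hexagonal orientation
  convention (above) and, more weakly, to ε.
* Thickness and midplane deformations are treated as decoupled, the
  midplane sector only at order-of-magnitude level.
* The nucleation criterion omits translational/rotational entropy
  prefactors of the bound state; its absolute scale is indicative only.
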