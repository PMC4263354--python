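# memrec

Membrane-mediated interactions between bacterial chemoreceptor trimers:
thickness-deformation energetics, lattice architecture, and signaling
cooperativity.

## The problem

Bacterial chemoreceptors assemble into extended two-dimensional honeycomb
lattices of trimers-of-dimers in the cytoplasmic membrane, with a
conserved ~12 nm lattice constant and a well-defined face-on relative
orientation of neighbouring trimers.  Like other transmembrane proteins,
chemoreceptor trimers have a hydrophobic thickness that need not match
the bilayer's; the resulting local thickness deformations of the lipid
bilayer overlap between neighbouring trimers and produce
membrane-mediated forces — attractive at short range, weakly repulsive at
intermediate range, and strongly *directional* because of the trimers'
three-fold symmetry.  `memrec` implements a quantitative elastic model of
these interactions for researchers in membrane biophysics and bacterial
chemotaxis: it computes anisotropic trimer–trimer pair potentials, ranks
candidate lattice architectures, estimates how few trimers suffice to
nucleate clusters, quantifies curvature-driven localization of lattices
to the cell poles, and evaluates the membrane's contribution to
piston-model signaling and to cooperativity between neighbouring trimers.

## The model

The bilayer is described by the deviation *u*(x, y) of the leaflet
hydrophobic half-thickness from its relaxed value *a*, with elastic energy

```
G[u] = ∫ dx dy [ (K_b/2)(∇²u)²  +  (K_t/2)(u/a)²  +  (τ/2)(∇u)²  +  τ u/a ]
```

where K_b is the bilayer bending modulus (20 k_BT), K_t the
thickness-deformation stiffness (60 k_BT/nm²), and τ the membrane
tension.  A trimer is a rigid inclusion with three-fold cross-section
r(θ) = R[1 + ε cos 3(θ − ω)] (R = 3.1 nm, ε = 0.2) that pins the
thickness at its boundary to its hydrophobic half-thickness mismatch
w − a (E. coli/Trg preset: a = 1.4 nm, w = 1.8 nm).  Minimisers of G
satisfy K_b∇⁴u − τ∇²u + (K_t/a²)u = const; the two characteristic roots
are a complex-conjugate pair at sub-degenerate tension, so deformations
relax over a ~1.3 nm decay length with a damped oscillation (thickness
overshoot).  Multi-inclusion boundary-value problems are solved by
least-squares collocation in decaying cylindrical harmonics
K_n(√ν± ρ)e^(inθ) about each trimer, and every energy is evaluated from
exact boundary-term integrals.  An independent finite-difference
relaxation oracle verifies the series solver on randomized
configurations.  Interaction energies are differences

```
G_int(d, ω₁, ω₂) = G_pair − G_iso,1 − G_iso,2 ,
```

lattice energies are half-sums of pairwise bond energies, and the
mesoscale estimates (lattice-gas nucleation threshold, conical-inclusion
curvature sensing) are closed forms built on the computed bond energies.

## Worked example

```
$ memrec selftest
decay length: 1.271 nm
face-on contact: d=6.170 nm, G=-26.15 kBT
tip-on contact:  d=8.240 nm, G=-12.23 kBT
selftest PASSED
```

Two trimers confronting each other face-on may approach to a centre
distance of 6.17 nm (a 0.8 nm edge-to-edge gap set by finite lipid and
trimer size); merging their deformation fields there releases 26 k_BT
relative to two isolated trimers — far more than the 12 k_BT released in
the tip-on orientation at its own steric minimum (8.24 nm).  The ~14 k_BT
orientation preference selects the face-on honeycomb architecture
observed *in vivo*.

```
$ memrec nucleation
 face_on_bond_kBT  spacing_nm  membrane_area_nm2  critical_trimer_number
       -12.944453    6.928203       9.424778e+06               34.645997
```

At the observed lattice separation (12 nm lattice constant / √3 ≈ 6.93
nm) a face-on bond is worth −12.9 k_BT, so the lattice-gas condensation
threshold in a 1 µm × 3 µm cell is reached with only a few tens of
trimers: membrane-mediated attraction alone can nucleate clusters at
very dilute receptor concentrations.

```
$ memrec cooperativity
 n_off_neighbors  transition_energy_kBT  per_neighbor_shift_kBT
               0             -21.478708                     NaN
               1             -23.074976               -1.596268
               2             -24.671244               -1.596268
               3             -26.267512               -1.596268
```

Within the piston model (0.16 nm thickness change between signaling
states), each face-on neighbour in the off state lowers the membrane
contribution to a trimer's on→off transition energy by ~1.6 k_BT — a
membrane-mediated route to cooperative signaling.  (The large constant
offset is the isolated-trimer membrane term, which must be compensated by
internal protein contributions since receptors operate near zero
transition energy.)

Other entry points: `memrec pair`, `memrec gateway`, `memrec lattice`,
`memrec localization`, `memrec figure <id>`, or the Python API
(`memrec.pair_energy`, `memrec.architecture_comparison`, ...).

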