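"""Per-trimer lattice energetics and architecture comparison.

Lattice energies are built from pairwise trimer-trimer potentials: the
energy per trimer is half the sum of the bond energies from a central
site to all neighbours within the included shells (each bond shared by
two trimers).  For shell 1 this reduces exactly to (coordination/2) times
the nearest-neighbour pair energy.  Longer-range shells evaluate the same
pair potential at the shell distances and relative orientations dictated
by the lattice's orientation rule.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .elastic import MembraneParams
from .geometry import (
    InclusionShape,
    LatticeSpec,
    PairConfiguration,
    lattice_sites,
    min_center_distance,
)
from .pair import pair_energy


__all__ = [
    "LatticeEnergyResult",
    "bond_configurations",
    "energy_per_trimer",
    "architecture_comparison",
    "crossover_scan",
    "steric_minimum_spacing",
]

_THIRD = 2.0 * math.pi / 3.0


@dataclass
class LatticeEnergyResult:
    spec: LatticeSpec
    energy_per_trimer: float
    shells_included: int
    bond_energies: pd.DataFrame  # shell, distance, omega1, omega2, count, energy


def bond_configurations(spec: LatticeSpec, shells: int):
    """Distinct (shell, d, omega1, omega2, multiplicity) bonds of the central site.

    Orientations are reduced to the bond frame (bond along +x) and folded
    by the trimers' 2 pi / 3 symmetry.
    """
    def fold(omega: float) -> float:
        om = omega % _THIRD
        if om > _THIRD - 1e-6:
            om = 0.0
        return om

    sites = lattice_sites(spec, shells)
    central = sites[0]
    counts: dict[tuple, int] = {}
    exact: dict[tuple, tuple] = {}
    for site in sites[1:]:
        x, y = site.position
        d = math.hypot(x, y)
        phi = math.atan2(y, x)
        om1 = fold(central.orientation - phi)
        om2 = fold(site.orientation - phi)
        key = (site.shell, round(d, 6), round(om1, 6), round(om2, 6))
        counts[key] = counts.get(key, 0) + 1
        exact.setdefault(key, (site.shell, d, om1, om2))
    return [(*exact[key], n) for key, n in sorted(counts.items())]


def steric_minimum_spacing(
    spec: LatticeSpec, shape: InclusionShape, clearance: float = 0.8
) -> float:
    """Smallest nearest-neighbour distance compatible with the clearance."""
    probe = LatticeSpec(spec.symmetry, max(spec.nearest_neighbor_distance, 1.0))
    bonds = [b for b in bond_configurations(probe, 1) if b[0] == 1]
    return max(
        min_center_distance(shape, shape, (om1, om2), clearance)
        for _, _, om1, om2, _ in bonds
    )


def energy_per_trimer(
    spec: LatticeSpec,
    shapes,
    params: MembraneParams,
    shells: int = 1,
    *,
    clearance: float = 0.8,
    mismatches=None,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> LatticeEnergyResult:
    """Membrane-mediated interaction energy per trimer (k_BT) in a lattice."""
    shape = shapes[0] if isinstance(shapes, (tuple, list)) else shapes
    d_min = steric_minimum_spacing(spec, shape, clearance)
    if spec.nearest_neighbor_distance < d_min - 1e-6:
        raise ValueError(
            f"spacing {spec.nearest_neighbor_distance:.3f} nm is below the steric "
            f"minimum {d_min:.3f} nm for {spec.symmetry}"
        )
    rows = []
    total = 0.0
    for shell, d, om1, om2, count in bond_configurations(spec, shells):
        g = pair_energy(
            PairConfiguration(d, om1, om2),
            shape,
            params,
            mismatches,
            n_modes=n_modes,
            slope_bc=slope_bc,
        )
        rows.append((shell, d, om1, om2, count, g))
        total += 0.5 * count * g
    bonds = pd.DataFrame(
        rows, columns=["shell", "distance_nm", "omega1", "omega2", "count", "energy_kBT"]
    )
    return LatticeEnergyResult(
        spec=spec, energy_per_trimer=total, shells_included=shells, bond_energies=bonds
    )


def architecture_comparison(
    shapes,
    params: MembraneParams,
    d_grids: dict | None = None,
    *,
    clearance: float = 0.8,
    shells: int = 1,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> pd.DataFrame:
    """Minimum lattice energy per architecture, ranked (most favourable first).

    ``d_grids`` maps symmetry tags to candidate nearest-neighbour
    distances; by default each architecture is scanned from its steric
    minimum outward.  Spacings below the steric minimum are dropped.
    """
    shape = shapes[0] if isinstance(shapes, (tuple, list)) else shapes
    symmetries = ("honeycomb_face_on", "honeycomb_tip_on", "hexagonal")
    records = []
    for sym in symmetries:
        d_min = steric_minimum_spacing(LatticeSpec(sym, 10.0), shape, clearance)
        if d_grids and sym in d_grids:
            grid = np.asarray(d_grids[sym], dtype=float)
            grid = grid[grid >= d_min - 1e-9]
            grid = np.unique(np.concatenate([[d_min], grid]))
        else:
            grid = np.unique(np.concatenate([[d_min], np.arange(d_min, d_min + 4.0, 0.25)]))
        energies = [
            energy_per_trimer(
                LatticeSpec(sym, float(d)), shape, params, shells,
                clearance=clearance, n_modes=n_modes, slope_bc=slope_bc,
            ).energy_per_trimer
            for d in grid
        ]
        i = int(np.argmin(energies))
        records.append(
            {
                "symmetry": sym,
                "optimal_spacing_nm": float(grid[i]),
                "steric_minimum_nm": float(d_min),
                "energy_per_trimer_kBT": float(energies[i]),
            }
        )
    df = pd.DataFrame(records).sort_values("energy_per_trimer_kBT").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def crossover_scan(
    spec: LatticeSpec,
    shapes,
    params: MembraneParams,
    over: str,
    grid,
    *,
    shells: int = 1,
    clearance: float = 0.8,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> pd.DataFrame:
    """Lattice energy per trimer along a thickness or tension grid.

    ``over`` is ``"monolayer_thickness"`` or ``"tension"``.  At zero
    tension the energy vanishes exactly where the bilayer monolayer
    thickness matches the trimer hydrophobic half-thickness; at crossover
    spacings the sign of the lattice energy differs between bilayers
    thicker and thinner than the trimer because the decay length grows
    with the monolayer thickness.
    """
    if over not in ("monolayer_thickness", "tension"):
        raise ValueError("over must be 'monolayer_thickness' or 'tension'")
    rows = []
    for value in np.asarray(grid, dtype=float):
        p = params.replace(**{over: float(value)})
        res = energy_per_trimer(
            spec, shapes, p, shells, clearance=clearance, n_modes=n_modes,
            slope_bc=slope_bc,
        )
        rows.append((value, res.energy_per_trimer))
    return pd.DataFrame(rows, columns=[over, "energy_per_trimer_kBT"])
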