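"""Mesoscale estimates: critical nucleation number and polar localization.

Two order-of-magnitude estimates complement the pair and lattice
energetics:

* **Nucleation.**  Treating the trimers as a dilute two-dimensional
  lattice gas of lipid-sized sites, membrane-mediated binding of strength
  ``E_b`` (a face-on bond) makes cluster formation thermodynamically
  favourable above the critical mole fraction ``x_c = exp(-|E_b|/k_BT)``.
  Converting ``x_c`` to a trimer count with the cell's membrane area
  gives the handful of trimers per cell at which nucleation-and-growth
  sets in.

* **Polar localization.**  Conically shaped trimers (contact angle
  ``alpha`` of the midplane at the trimer edge) prefer curved membrane.
  The mean curvature at the poles of a rod-shaped cell is about twice
  that of the cylindrical midcell, so each trimer gains a small midplane
  energy at the poles.  Two standard formulations bracket the estimate:
  a local curvature-frustration energy over the trimer footprint and a
  logarithmically regularised midplane boundary-value estimate; their
  spread defines the reported (lower, upper) interval.  The per-trimer
  difference is far below k_BT — single trimers cannot sense curvature —
  but grows linearly with lattice size, localizing large lattices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .elastic import MembraneParams
from .presets import LIPID_AREA_NM2


__all__ = [
    "CellGeometry",
    "ConicalShape",
    "critical_trimer_number",
    "midplane_energy_estimate",
    "midplane_pair_interaction",
    "localization_energy",
]


@dataclass(frozen=True)
class CellGeometry:
    """Membrane area and curvatures of a rod-shaped cell.

    Curvatures are mean curvatures in 1/nm; the pole (hemispherical cap,
    radius = cell radius r: H = 1/r) is twice as curved as the cylindrical
    midcell (H = 1/2r).
    """

    membrane_area: float
    pole_curvature: float
    midcell_curvature: float

    def __post_init__(self) -> None:
        if min(self.membrane_area, self.pole_curvature, self.midcell_curvature) <= 0:
            raise ValueError("areas and curvatures must be positive")
        if self.pole_curvature <= self.midcell_curvature:
            raise ValueError("pole must be more curved than midcell")

    @classmethod
    def ecoli(cls, radius_nm: float = 500.0, length_nm: float = 3000.0) -> "CellGeometry":
        """Rod of diameter 2r and total length L with hemispherical poles."""
        cyl = 2.0 * math.pi * radius_nm * (length_nm - 2.0 * radius_nm)
        caps = 4.0 * math.pi * radius_nm**2
        return cls(
            membrane_area=cyl + caps,
            pole_curvature=1.0 / radius_nm,
            midcell_curvature=1.0 / (2.0 * radius_nm),
        )


@dataclass(frozen=True)
class ConicalShape:
    """Conical trimer: midplane contact angle at the bilayer-trimer interface."""

    contact_angle: float = 0.1
    tilt: float = 0.0
    footprint_radius: float = 3.1

    def __post_init__(self) -> None:
        if abs(self.contact_angle) >= 0.5 or abs(self.tilt) >= 0.5:
            raise ValueError("angles must be small (|angle| < 0.5 rad)")
        if self.footprint_radius <= 0:
            raise ValueError("footprint_radius must be positive")


def critical_trimer_number(
    binding_energy: float,
    cell: CellGeometry,
    site_area: float = LIPID_AREA_NM2,
) -> float:
    """Critical trimer count for nucleation and growth.

    ``binding_energy`` (k_BT, must be negative) is the membrane-mediated
    face-on bond energy at the lattice separation of the condensed phase.
    The critical mole fraction ``x_c = exp(binding_energy / k_BT)`` (per
    lipid-sized site of area ``site_area``) is converted to a count with
    the cell's membrane area.  Depends only on the binding energy, never
    on any overall energy offset.
    """
    if binding_energy >= 0:
        raise ValueError("binding_energy must be negative (favourable)")
    if site_area <= 0:
        raise ValueError("site_area must be positive")
    x_c = math.exp(binding_energy)
    return x_c * cell.membrane_area / site_area


def _midplane_formulations(
    shape: ConicalShape,
    params: MembraneParams,
    background_curvature: float,
    outer_cutoff: float,
) -> tuple[float, float]:
    """Per-trimer midplane energy on a curved background, two formulations."""
    kappa = params.bending_modulus
    alpha = shape.contact_angle
    R = shape.footprint_radius
    mismatch_slope = alpha - background_curvature * R
    # (a) local curvature frustration over the footprint disc:
    #     (kappa/2) * pi R^2 * (2H - 2 alpha / R)^2
    e_local = 2.0 * math.pi * kappa * mismatch_slope**2
    # (b) exterior cone solution, log-regularised by tension or cell size
    if params.tension > 0:
        ell = min(math.sqrt(kappa / params.tension), outer_cutoff)
    else:
        ell = outer_cutoff
    ell = max(ell, math.e * R)  # keep the logarithm >= 1
    e_cone = math.pi * kappa * mismatch_slope**2 * math.log(ell / R)
    return (min(e_local, e_cone), max(e_local, e_cone))


def midplane_energy_estimate(
    shape: ConicalShape,
    params: MembraneParams,
    background_curvature: float,
    *,
    outer_cutoff: float = 500.0,
) -> tuple[float, float]:
    """Per-trimer midplane deformation energy (k_BT) as a (lower, upper) interval.

    ``background_curvature`` is the local mean curvature (1/nm) of the
    cell membrane; the two interval ends are the two model formulations
    described in the module docstring.
    """
    if abs(shape.contact_angle) >= 0.5:
        raise ValueError("contact angle outside the small-angle regime")
    return _midplane_formulations(shape, params, background_curvature, outer_cutoff)


def midplane_pair_interaction(
    shape1: ConicalShape,
    shape2: ConicalShape,
    distance: float,
    params: MembraneParams,
) -> float:
    """Far-field curvature-mediated pair repulsion estimate (k_BT).

    Order-of-magnitude estimate
    ``4 pi kappa (alpha1^2 + alpha2^2) (R / d)^4`` for two conical
    inclusions; always more than an order of magnitude below the
    thickness-mediated interactions at comparable separations for the
    E. coli preset.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    kappa = params.bending_modulus
    R = 0.5 * (shape1.footprint_radius + shape2.footprint_radius)
    return (
        4.0
        * math.pi
        * kappa
        * (shape1.contact_angle**2 + shape2.contact_angle**2)
        * (R / distance) ** 4
    )


def localization_energy(
    n_trimers: int,
    shape: ConicalShape,
    params: MembraneParams,
    cell: CellGeometry,
) -> tuple[float, float]:
    """Midcell-vs-pole energy difference (k_BT interval) for an N-trimer lattice.

    Linear in N by construction: each trimer contributes the per-trimer
    difference between the midplane energies at the midcell and at the
    pole.  For a single trimer the whole interval lies below 1 k_BT; for
    lattices of thousands of trimers the lower bound is far above k_BT,
    favouring the poles.
    """
    if n_trimers < 1:
        raise ValueError("n_trimers must be >= 1")
    lo_p, up_p = midplane_energy_estimate(shape, params, cell.pole_curvature)
    lo_m, up_m = midplane_energy_estimate(shape, params, cell.midcell_curvature)
    per_lo = min(lo_m - lo_p, up_m - up_p)
    per_up = max(lo_m - lo_p, up_m - up_p)
    return (n_trimers * per_lo, n_trimers * per_up)
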