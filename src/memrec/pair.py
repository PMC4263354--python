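"""Anisotropic membrane-mediated pair potentials between trimers.

The interaction energy of two inclusions is the total thickness-deformation
energy of the two-inclusion boundary-value problem minus the energies of
the two isolated inclusions,

    G_int(d, omega1, omega2) = G_pair - G_iso,1 - G_iso,2 ,

all evaluated with the same series truncation so that G_int -> 0 exactly
as the inclusions decouple.  Negative G_int means membrane-mediated
attraction.  For the E. coli preset the face-on potential exhibits three
regimes: strong short-range attraction (overlapping decay zones reduce
the joint deformation footprint), a weak intermediate-range repulsive
barrier (frustration between compressed and expanded annuli), and a
negligible oscillatory tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .elastic import MembraneParams
from .geometry import (
    InclusionShape,
    PairConfiguration,
    min_center_distance,
    _boundary_gap,
)
from .series import SeriesSolution, solve_inclusions


__all__ = [
    "PairPotentialCurve",
    "pair_energy",
    "pair_solution",
    "isolated_energy",
    "potential_curve",
    "gateway_path",
]


def _resolve_shapes(shapes, config: PairConfiguration):
    s1, s2 = shapes if isinstance(shapes, (tuple, list)) else (shapes, shapes)
    return (
        s1.with_orientation(config.orientation_1),
        s2.with_orientation(config.orientation_2),
    )


def isolated_energy(
    shape: InclusionShape,
    params: MembraneParams,
    mismatch: float | None = None,
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> float:
    """Deformation energy (k_BT) of one isolated trimer at truncation ``n_modes``."""
    if mismatch is None:
        mismatch = shape.mismatch(params)
    sol = solve_inclusions(
        params, [shape], [(0.0, 0.0)], [mismatch], n_modes=n_modes, slope_bc=slope_bc
    )
    return sol.energy()


def pair_solution(
    config: PairConfiguration,
    shapes,
    params: MembraneParams,
    mismatches=None,
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> SeriesSolution:
    """Series solution of the two-inclusion problem (for field export)."""
    s1, s2 = _resolve_shapes(shapes, config)
    if mismatches is None:
        mismatches = (s1.mismatch(params), s2.mismatch(params))
    return solve_inclusions(
        params,
        [s1, s2],
        config.centers,
        mismatches,
        n_modes=n_modes,
        slope_bc=slope_bc,
    )


def pair_energy(
    config: PairConfiguration,
    shapes,
    params: MembraneParams,
    mismatches=None,
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
    min_clearance: float = 0.0,
    check_convergence: bool = False,
    convergence_tol: float = 0.25,
) -> float:
    """Membrane-mediated interaction energy G_int in k_BT.

    Parameters
    ----------
    config : PairConfiguration
        Centre distance and orientations (bond along +x).
    shapes : InclusionShape or (InclusionShape, InclusionShape)
        Cross-sections; orientations are overridden by ``config``.
    mismatches : (float, float), optional
        Per-inclusion hydrophobic half-thickness mismatches; defaults to
        the shapes' thicknesses against ``params``.
    min_clearance : float
        Smallest admissible edge-to-edge gap; configurations below it (or
        overlapping) raise ``ValueError``.
    check_convergence : bool
        Re-solve at truncation ``n_modes - 2`` and raise ``RuntimeError``
        with diagnostics if G_int changed by more than ``convergence_tol``.
    """
    s1, s2 = _resolve_shapes(shapes, config)
    gap = _boundary_gap(config.center_distance, s1, s2, s1.orientation, s2.orientation)
    if gap < min_clearance or gap <= 0.0:
        raise ValueError(
            f"centre distance {config.center_distance:.3f} nm gives edge-to-edge gap "
            f"{gap:.3f} nm, below the steric minimum clearance {min_clearance:.3f} nm"
        )
    if mismatches is None:
        mismatches = (s1.mismatch(params), s2.mismatch(params))

    def g_at(n: int) -> float:
        pair = solve_inclusions(
            params, [s1, s2], config.centers, mismatches, n_modes=n, slope_bc=slope_bc
        ).energy()
        iso1 = isolated_energy(s1, params, mismatches[0], n_modes=n, slope_bc=slope_bc)
        iso2 = isolated_energy(s2, params, mismatches[1], n_modes=n, slope_bc=slope_bc)
        return pair - iso1 - iso2

    g = g_at(n_modes)
    if check_convergence:
        g_prev = g_at(n_modes - 2)
        if abs(g - g_prev) > convergence_tol:
            raise RuntimeError(
                f"series not converged: G_int changed by {abs(g - g_prev):.3f} k_BT "
                f"between truncation orders {n_modes - 2} and {n_modes} "
                f"(tolerance {convergence_tol}); raise n_modes"
            )
    return g


@dataclass
class PairPotentialCurve:
    """Tabulated interaction potential G_int(d) for a fixed orientation preset."""

    orientation: str
    distances: np.ndarray
    energies: np.ndarray
    steric_minimum: float
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_distance_nm": self.distances,
                "orientation": self.orientation,
                "interaction_energy_kBT": self.energies,
            }
        )


_ORIENTATIONS = {
    "tip-on": PairConfiguration.tip_on,
    "face-on": PairConfiguration.face_on,
}


def potential_curve(
    orientation: str,
    d_grid,
    shapes,
    params: MembraneParams,
    *,
    clearance: float = 0.8,
    mismatches=None,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> PairPotentialCurve:
    """Interaction potential along a centre-distance grid.

    The curve starts at the steric-minimum distance for the orientation
    (the curve's end point); grid values below it are dropped.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of {sorted(_ORIENTATIONS)}"
        )
    make = _ORIENTATIONS[orientation]
    s1, s2 = shapes if isinstance(shapes, (tuple, list)) else (shapes, shapes)
    om = make(1.0)  # orientations only
    d_min = min_center_distance(
        s1, s2, (om.orientation_1, om.orientation_2), clearance
    )
    d_grid = np.asarray(d_grid, dtype=float)
    d_grid = np.unique(np.concatenate([[d_min], d_grid[d_grid > d_min + 1e-9]]))
    energies = np.array(
        [
            pair_energy(
                make(d), (s1, s2), params, mismatches, n_modes=n_modes, slope_bc=slope_bc
            )
            for d in d_grid
        ]
    )
    return PairPotentialCurve(
        orientation=orientation,
        distances=d_grid,
        energies=energies,
        steric_minimum=d_min,
        metadata={
            "params": params,
            "shape": (s1, s2),
            "n_modes": n_modes,
            "slope_bc": slope_bc,
            "clearance": clearance,
        },
    )


def gateway_path(
    shapes,
    params: MembraneParams,
    clearance: float = 0.8,
    *,
    n_points: int = 13,
    mismatches=None,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> pd.DataFrame:
    """Symmetric rotation family from the tip-on to the face-on configuration.

    The two trimers counter-rotate (omega1 = gamma, omega2 = pi/3 - gamma,
    gamma in [0, pi/3]), preserving mirror symmetry about the bond's
    perpendicular bisector, with each configuration at its own
    steric-minimum centre distance for the given clearance.  Energies are
    reported relative to the tip-on end point.
    """
    s1, s2 = shapes if isinstance(shapes, (tuple, list)) else (shapes, shapes)
    gammas = np.linspace(0.0, math.pi / 3.0, n_points)
    rows = []
    for gamma in gammas:
        om1, om2 = float(gamma), float(math.pi / 3.0 - gamma)
        d = min_center_distance(s1, s2, (om1, om2), clearance)
        g = pair_energy(
            PairConfiguration(d, om1, om2),
            (s1, s2),
            params,
            mismatches,
            n_modes=n_modes,
            slope_bc=slope_bc,
        )
        rows.append((d, om1, om2, g))
    df = pd.DataFrame(
        rows, columns=["center_distance_nm", "omega1", "omega2", "interaction_energy_kBT"]
    )
    df["delta_g_kBT"] = df["interaction_energy_kBT"] - df["interaction_energy_kBT"].iloc[0]
    return df
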