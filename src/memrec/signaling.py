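"""Piston-model signaling states and membrane-mediated cooperativity.

Chemotactic signaling slides one transmembrane helix of each receptor
dimer by ~0.16 nm (the "piston" model), which we represent as a uniform
0.16 nm difference in trimer hydrophobic thickness between the on and off
signaling states (half-thickness difference 0.08 nm, centred on the
resting thickness; the on state is the thicker one by default).  The
membrane then contributes to the on/off transition energy of a trimer
both through its isolated deformation energy and, in a lattice, through
state-dependent pair interactions with its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .elastic import MembraneParams
from .geometry import InclusionShape, PairConfiguration, FACE_ON
from .pair import pair_energy, isolated_energy
from .presets import FACE_ON_SPACING_NM, PISTON_SHIFT_NM


__all__ = [
    "TrimerState",
    "make_states",
    "transition_energy_single",
    "mixed_pair_energy",
    "cooperativity_shift",
    "cooperativity_table",
]


@dataclass(frozen=True)
class TrimerState:
    """A signaling state with its hydrophobic half-thickness (nm)."""

    label: str
    hydrophobic_half_thickness: float


def make_states(
    base_half_thickness: float = 1.8,
    piston_shift: float = PISTON_SHIFT_NM,
    *,
    thicker: str = "on",
) -> tuple[TrimerState, TrimerState]:
    """The (on, off) states, hydrophobic thickness differing by ``piston_shift``.

    ``piston_shift`` is the full-thickness difference; the two states'
    half-thicknesses are ``base ± piston_shift/4`` so that
    ``|thickness(on) - thickness(off)| = piston_shift``.  ``thicker``
    selects which state has the larger hydrophobic thickness.
    """
    if thicker not in ("on", "off"):
        raise ValueError("thicker must be 'on' or 'off'")
    dw = piston_shift / 4.0
    sign = 1.0 if thicker == "on" else -1.0
    on = TrimerState("on", base_half_thickness + sign * dw)
    off = TrimerState("off", base_half_thickness - sign * dw)
    return on, off


def transition_energy_single(
    params: MembraneParams,
    shape: InclusionShape,
    states: tuple[TrimerState, TrimerState],
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> float:
    """Membrane contribution to the on -> off transition energy (k_BT).

    Difference of isolated-trimer deformation energies, E(off) - E(on).
    Because the deformation energy is quadratic in the effective mismatch,
    the sign changes exactly where the monolayer thickness equals the mean
    of the two states' half-thicknesses (at zero tension).
    """
    on, off = states
    e = {}
    for st in (on, off):
        mis = st.hydrophobic_half_thickness - params.monolayer_thickness
        e[st.label] = isolated_energy(
            shape, params, mis, n_modes=n_modes, slope_bc=slope_bc
        )
    return e["off"] - e["on"]


def mixed_pair_energy(
    config: PairConfiguration,
    shapes,
    params: MembraneParams,
    state1: TrimerState,
    state2: TrimerState,
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> float:
    """Pair interaction energy for trimers in (possibly different) states."""
    mis = (
        state1.hydrophobic_half_thickness - params.monolayer_thickness,
        state2.hydrophobic_half_thickness - params.monolayer_thickness,
    )
    return pair_energy(
        config, shapes, params, mis, n_modes=n_modes, slope_bc=slope_bc
    )


def cooperativity_shift(
    n_off_neighbors: int,
    params: MembraneParams,
    shape: InclusionShape,
    states: tuple[TrimerState, TrimerState],
    *,
    spacing: float = FACE_ON_SPACING_NM,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> float:
    """On -> off transition energy of a central trimer in a face-on honeycomb.

    The central trimer has ``n_off_neighbors`` of its three face-on
    nearest neighbours in the off state (the rest on), at the observed
    lattice spacing.  Pairwise additivity makes the result affine in n:
    each off neighbour shifts the transition energy by the same amount
    -(G_on,on + G_off,off - 2 G_on,off)/... (see cooperativity_table).
    """
    if not 0 <= n_off_neighbors <= 3:
        raise ValueError("n_off_neighbors must be in 0..3")
    on, off = states
    cfg = PairConfiguration(spacing, *FACE_ON)
    kw = dict(n_modes=n_modes, slope_bc=slope_bc)
    g = {
        (a.label, b.label): mixed_pair_energy(cfg, shape, params, a, b, **kw)
        for a in (on, off)
        for b in (on, off)
    }
    dg0 = transition_energy_single(params, shape, states, n_modes=n_modes, slope_bc=slope_bc)
    n = n_off_neighbors
    return (
        dg0
        + n * (g[("off", "off")] - g[("on", "off")])
        + (3 - n) * (g[("off", "on")] - g[("on", "on")])
    )


def cooperativity_table(
    params: MembraneParams,
    shape: InclusionShape,
    states: tuple[TrimerState, TrimerState],
    *,
    spacing: float = FACE_ON_SPACING_NM,
    n_modes: int = 12,
    slope_bc: str = "clamped",
) -> pd.DataFrame:
    """Transition energies for n = 0..3 off neighbours, plus the per-neighbour shift."""
    vals = [
        cooperativity_shift(
            n, params, shape, states, spacing=spacing, n_modes=n_modes, slope_bc=slope_bc
        )
        for n in range(4)
    ]
    df = pd.DataFrame({"n_off_neighbors": range(4), "transition_energy_kBT": vals})
    df["per_neighbor_shift_kBT"] = df["transition_energy_kBT"].diff()
    return df
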