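"""Run configuration, randomized case generation and figure-table reproduction."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd
import yaml

from .elastic import MembraneParams
from .geometry import InclusionShape, PairConfiguration, LatticeSpec, min_center_distance
from .pair import potential_curve, gateway_path
from .lattice import energy_per_trimer, architecture_comparison, crossover_scan, steric_minimum_spacing
from .signaling import make_states, cooperativity_shift, transition_energy_single
from .presets import preset, FACE_ON_SPACING_NM


__all__ = [
    "RunConfig",
    "RandomCase",
    "random_case_generator",
    "reproduce_figure_table",
    "write_table",
    "FIGURE_IDS",
]


def _package_version() -> str:
    try:
        return _pkg_version("memrec")
    except Exception:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Everything that determines a run: preset, overrides, grids, seed."""

    preset: str = "ecoli"
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    output: str | None = None

    def resolved(self) -> dict:
        params, shape = preset(self.preset, **self.overrides)
        return {
            "preset": self.preset,
            "seed": self.seed,
            "membrane": asdict(params),
            "shape": asdict(shape),
            "version": _package_version(),
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """CSV output with a YAML provenance sidecar (<path>.meta.yaml)."""
    df.to_csv(path, index=False, float_format="%.10g")
    meta = (config or RunConfig()).resolved()
    meta["config_hash"] = (config or RunConfig()).config_hash
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


@dataclass
class RandomCase:
    params: MembraneParams
    shape1: InclusionShape
    shape2: InclusionShape
    config: PairConfiguration

    @property
    def mismatches(self):
        return (
            self.shape1.mismatch(self.params),
            self.shape2.mismatch(self.params),
        )


def random_case_generator(seed: int, clearance: float = 0.8):
    """Endless stream of sterically valid randomized pair configurations.

    Parameter ranges bracket the E. coli preset: monolayer thickness
    1.2-1.7 nm, hydrophobic mismatch of either sign up to 0.5 nm, tension
    from 0 to rupture scale (2 k_BT/nm^2), three-fold amplitude 0-0.3,
    mean radius 2.6-3.6 nm, arbitrary orientations and centre distances
    from the steric minimum to the minimum plus 4 nm.
    """
    rng = np.random.default_rng(seed)
    third = 2.0 * math.pi / 3.0
    while True:
        a = rng.uniform(1.2, 1.7)
        mis = rng.uniform(0.1, 0.5) * rng.choice([-1.0, 1.0])
        tau = rng.uniform(0.0, 2.0)
        eps = rng.uniform(0.0, 0.3)
        R = rng.uniform(2.6, 3.6)
        om1, om2 = rng.uniform(0.0, third, size=2)
        params = MembraneParams(tension=float(tau), monolayer_thickness=float(a))
        shape = InclusionShape(
            mean_radius=float(R),
            threefold_amplitude=float(eps),
            hydrophobic_half_thickness=float(a + mis),
        )
        s1 = shape.with_orientation(float(om1))
        s2 = shape.with_orientation(float(om2))
        d_min = min_center_distance(s1, s2, (float(om1), float(om2)), clearance)
        d = d_min + rng.uniform(0.0, 4.0)
        yield RandomCase(
            params=params,
            shape1=s1,
            shape2=s2,
            config=PairConfiguration(float(d), float(om1), float(om2)),
        )


FIGURE_IDS = (
    "F2A", "F2B", "F2C", "F3A", "F3B", "F4A", "F4B", "F5B", "S5", "S6", "S7",
)

_THICKNESS_GRID = (1.2, 1.3, 1.4, 1.5, 1.6, 1.7)
_TENSION_GRID = (0.0, 0.5, 1.0, 2.0)


def reproduce_figure_table(figure_id: str, *, fast: bool = False) -> pd.DataFrame:
    """Data table underlying one of the named interaction/lattice figures.

    Axis columns match the corresponding figure's variables.  Deterministic:
    identical calls produce identical tables.  ``fast`` coarsens grids.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; known: {FIGURE_IDS}")
    params, shape = preset("ecoli")
    step = 0.5 if fast else 0.25
    d_grid = np.arange(5.5, 14.0 + step / 2, step)
    n_gw = 7 if fast else 13

    if figure_id == "F2A":
        frames = []
        for orient in ("face-on", "tip-on"):
            curve = potential_curve(orient, d_grid, shape, params)
            frames.append(curve.to_dataframe())
        return pd.concat(frames, ignore_index=True)

    if figure_id == "F2B":
        frames = []
        for a in _THICKNESS_GRID:
            p = params.replace(monolayer_thickness=a)
            df = potential_curve("face-on", d_grid, shape, p).to_dataframe()
            df.insert(0, "monolayer_thickness_nm", a)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    if figure_id == "F2C":
        frames = []
        for tau in _TENSION_GRID:
            p = params.replace(tension=tau)
            df = potential_curve("face-on", d_grid, shape, p).to_dataframe()
            df.insert(0, "tension_kBT_nm2", tau)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    if figure_id in ("F3A", "F3B"):
        frames = []
        values = _THICKNESS_GRID[1:4] if figure_id == "F3A" else _TENSION_GRID[:3]
        key = "monolayer_thickness" if figure_id == "F3A" else "tension"
        for v in values:
            p = params.replace(**{key: v})
            df = gateway_path(shape, p, n_points=n_gw)
            df.insert(0, f"{key}_value", v)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    if figure_id == "F4A":
        frames = []
        for sym in ("honeycomb_face_on", "honeycomb_tip_on", "hexagonal"):
            d_min = steric_minimum_spacing(LatticeSpec(sym, 10.0), shape)
            for d in np.arange(d_min, d_min + 4.0 + 1e-9, step * 2):
                res = energy_per_trimer(LatticeSpec(sym, float(d)), shape, params)
                frames.append((sym, float(d), res.energy_per_trimer))
        return pd.DataFrame(
            frames, columns=["symmetry", "spacing_nm", "energy_per_trimer_kBT"]
        )

    if figure_id in ("F4B", "S5"):
        comparison = architecture_comparison(shape, params)
        frames = []
        for _, row in comparison.iterrows():
            spec = LatticeSpec(row["symmetry"], row["optimal_spacing_nm"])
            scan = crossover_scan(
                spec, shape, params, "monolayer_thickness", _THICKNESS_GRID
            )
            scan.insert(0, "symmetry", row["symmetry"])
            scan.insert(1, "spacing_nm", row["optimal_spacing_nm"])
            frames.append(scan)
            tens = crossover_scan(spec, shape, params, "tension", _TENSION_GRID)
            tens.insert(0, "symmetry", row["symmetry"])
            tens.insert(1, "spacing_nm", row["optimal_spacing_nm"])
            frames.append(tens)
        return pd.concat(frames, ignore_index=True)

    if figure_id == "F5B":
        states = make_states(shape.hydrophobic_half_thickness)
        rows = []
        for a in _THICKNESS_GRID:
            p = params.replace(monolayer_thickness=a)
            for n in range(4):
                rows.append(
                    ("monolayer_thickness", a, n,
                     cooperativity_shift(n, p, shape, states))
                )
        for tau in _TENSION_GRID:
            p = params.replace(tension=tau)
            for n in range(4):
                rows.append(
                    ("tension", tau, n, cooperativity_shift(n, p, shape, states))
                )
        return pd.DataFrame(
            rows, columns=["axis", "value", "n_off_neighbors", "transition_energy_kBT"]
        )

    if figure_id == "S6":
        frames = []
        for sym in ("honeycomb_face_on", "honeycomb_tip_on", "hexagonal"):
            d_min = steric_minimum_spacing(LatticeSpec(sym, 10.0), shape)
            for d in np.arange(d_min, d_min + 3.0 + 1e-9, 0.5 if fast else 0.25):
                for shells in (1, 2, 3):
                    res = energy_per_trimer(
                        LatticeSpec(sym, float(d)), shape, params, shells
                    )
                    frames.append((sym, float(d), shells, res.energy_per_trimer))
        return pd.DataFrame(
            frames,
            columns=["symmetry", "spacing_nm", "shells", "energy_per_trimer_kBT"],
        )

    # S7: single-trimer transition energy vs thickness and tension
    states = make_states(shape.hydrophobic_half_thickness)
    rows = []
    for a in _THICKNESS_GRID:
        p = params.replace(monolayer_thickness=a)
        rows.append(("monolayer_thickness", a, transition_energy_single(p, shape, states)))
    for tau in _TENSION_GRID:
        p = params.replace(tension=tau)
        rows.append(("tension", tau, transition_energy_single(p, shape, states)))
    return pd.DataFrame(rows, columns=["axis", "value", "transition_energy_kBT"])
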