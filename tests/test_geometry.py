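"""Trimer cross-section, steric minima and lattice generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memrec import (
    InclusionShape,
    LatticeSpec,
    min_center_distance,
    lattice_sites,
    area_per_trimer,
    FACE_ON,
    TIP_ON,
)
from memrec.geometry import _boundary_gap


def test_unperturbed_boundary_is_circle():
    shape = InclusionShape(threefold_amplitude=0.0)
    th = np.linspace(0, 2 * np.pi, 100)
    assert np.allclose(shape.boundary_radius(th), shape.mean_radius)


@given(
    theta=st.floats(-10.0, 10.0),
    omega=st.floats(0.0, 2 * math.pi),
    eps=st.floats(0.0, 0.5),
)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_boundary_threefold_symmetry_and_rotation(theta, omega, eps):
    shape = InclusionShape(threefold_amplitude=eps, orientation=omega)
    r = shape.boundary_radius(theta)
    assert r == pytest.approx(shape.boundary_radius(theta + 2 * math.pi / 3), rel=1e-12)
    # rotating the trimer shifts the pattern
    delta = 0.37
    rotated = shape.with_orientation(omega + delta)
    assert rotated.boundary_radius(theta) == pytest.approx(
        shape.boundary_radius(theta - delta), rel=1e-12
    )


@given(
    radius=st.floats(1.0, 5.0),
    clearance=st.floats(0.0, 2.0),
)
@settings(derandomize=True, max_examples=20, deadline=None)
def test_min_distance_of_circles_is_closed_form(radius, clearance):
    circle = InclusionShape(mean_radius=radius, threefold_amplitude=0.0)
    d = min_center_distance(circle, circle, (0.0, 0.0), clearance)
    assert d == pytest.approx(2 * radius + clearance, abs=2e-4)


def test_tip_on_contacts_sooner_than_face_on(trg):
    """Brute-force check: tips pointing at each other collide at larger d."""
    d_tip = min_center_distance(trg, trg, TIP_ON, 0.8)
    d_face = min_center_distance(trg, trg, FACE_ON, 0.8)
    assert d_tip > d_face
    # returned distances realise the clearance exactly
    for (om1, om2), d in [(TIP_ON, d_tip), (FACE_ON, d_face)]:
        gap = _boundary_gap(d, trg, trg, om1, om2, n=2880)
        assert gap == pytest.approx(0.8, abs=2e-3)


def test_min_distance_periodic_and_continuous_in_orientation(trg):
    third = 2 * math.pi / 3
    oms = np.linspace(0.0, third, 13)
    ds = [min_center_distance(trg, trg, (om, math.pi / 3), 0.8) for om in oms]
    assert ds[0] == pytest.approx(ds[-1], abs=1e-6)  # 2pi/3 periodic
    assert np.abs(np.diff(ds)).max() < 0.4  # no jumps on the grid


# --- lattices -----------------------------------------------------------


def _brute_force_shell_counts(symmetry: str, d: float, shells: int):
    """Independent enumeration of neighbour-shell multiplicities."""
    pts = []
    if symmetry == "hexagonal":
        a1 = np.array([d, 0.0])
        a2 = np.array([d / 2, d * math.sqrt(3) / 2])
        for i in range(-6, 7):
            for j in range(-6, 7):
                pts.append(i * a1 + j * a2)
    else:
        a1 = math.sqrt(3) * d * np.array([math.sqrt(3) / 2, 0.5])
        a2 = math.sqrt(3) * d * np.array([math.sqrt(3) / 2, -0.5])
        for i in range(-6, 7):
            for j in range(-6, 7):
                pts.append(i * a1 + j * a2)
                pts.append(i * a1 + j * a2 + np.array([d, 0.0]))
    dist = sorted(
        {round(float(np.hypot(*p)), 6) for p in pts if float(np.hypot(*p)) > 1e-9}
    )
    counts = []
    for dd in dist[:shells]:
        counts.append(
            sum(1 for p in pts if abs(float(np.hypot(*p)) - dd) < 1e-6)
        )
    return counts


@pytest.mark.parametrize(
    "symmetry,coordination",
    [("hexagonal", 6), ("honeycomb_face_on", 3), ("honeycomb_tip_on", 3)],
)
def test_first_shell_coordination(symmetry, coordination):
    spec = LatticeSpec(symmetry, 7.0)
    sites = lattice_sites(spec, 1)
    shell1 = [s for s in sites if s.shell == 1]
    assert len(shell1) == coordination
    for s in shell1:
        assert math.hypot(*s.position) == pytest.approx(7.0, rel=1e-9)


@pytest.mark.parametrize("symmetry", ["hexagonal", "honeycomb_face_on", "honeycomb_tip_on"])
def test_shell_multiplicities_match_enumeration(symmetry):
    spec = LatticeSpec(symmetry, 6.5)
    sites = lattice_sites(spec, 3)
    got = [sum(1 for s in sites if s.shell == k) for k in (1, 2, 3)]
    assert got == _brute_force_shell_counts(symmetry, 6.5, 3)


def test_face_on_honeycomb_bonds_are_face_on():
    """Every nearest-neighbour bond realises the face-on configuration."""
    from memrec.lattice import bond_configurations

    spec = LatticeSpec("honeycomb_face_on", 7.0)
    third = 2 * math.pi / 3
    for shell, d, om1, om2, count in bond_configurations(spec, 1):
        if shell != 1:
            continue
        assert (om1 % third, om2 % third) == (
            pytest.approx(FACE_ON[0] % third, abs=1e-9),
            pytest.approx(FACE_ON[1] % third, abs=1e-9),
        )
    spec = LatticeSpec("honeycomb_tip_on", 7.0)
    for shell, d, om1, om2, count in bond_configurations(spec, 1):
        if shell != 1:
            continue
        assert (om1 % third, om2 % third) == (
            pytest.approx(TIP_ON[0] % third, abs=1e-9),
            pytest.approx(TIP_ON[1] % third, abs=1e-9),
        )


def test_lattice_generation_deterministic():
    spec = LatticeSpec("honeycomb_face_on", 6.93)
    assert lattice_sites(spec, 2) == lattice_sites(spec, 2)


def test_unknown_symmetry_rejected():
    with pytest.raises(ValueError, match="unknown symmetry"):
        LatticeSpec("kagome", 7.0)


def test_area_per_trimer_identities():
    d = 6.93
    hexa = area_per_trimer(LatticeSpec("hexagonal", d))
    honey = area_per_trimer(LatticeSpec("honeycomb_face_on", d))
    assert hexa == pytest.approx(math.sqrt(3) / 2 * d * d, rel=1e-14)
    assert honey == pytest.approx(1.5 * hexa, rel=1e-14)  # exactly 50% more


@given(d=st.floats(1.0, 20.0), lam=st.floats(0.1, 5.0))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_area_scaling(d, lam):
    a1 = area_per_trimer(LatticeSpec("honeycomb_tip_on", d))
    a2 = area_per_trimer(LatticeSpec("honeycomb_tip_on", lam * d))
    assert a2 == pytest.approx(lam**2 * a1, rel=1e-12)
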