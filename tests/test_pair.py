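"""Pair potentials: symmetries, regimes, gateway path and the grid oracle."""

import math

import numpy as np
import pytest

from memrec import (
    PairConfiguration,
    pair_energy,
    potential_curve,
    gateway_path,
    fd_oracle_energy,
    fd_total_energy,
    single_inclusion_energy,
    FACE_ON,
    TIP_ON,
)

THIRD = 2 * math.pi / 3


def test_zero_mismatch_gives_zero_interaction(ecoli_params, trg, d_face):
    cfg = PairConfiguration(d_face, *FACE_ON)
    g = pair_energy(cfg, trg, ecoli_params, mismatches=(0.0, 0.0))
    assert g == pytest.approx(0.0, abs=1e-12)


def test_exact_symmetries(ecoli_params, trg):
    """Pi-rotation about the midpoint, mirror, and 2pi/3 trimer symmetry."""
    d = 8.0
    om1, om2 = 0.21, 0.55
    g = pair_energy(PairConfiguration(d, om1, om2), trg, ecoli_params)
    # relabelling the trimers = pi rotation: (om1, om2) -> (om2+pi, om1+pi)
    g_rot = pair_energy(
        PairConfiguration(d, om2 + math.pi, om1 + math.pi), trg, ecoli_params
    )
    # mirror about the bond axis
    g_mir = pair_energy(PairConfiguration(d, -om1, -om2), trg, ecoli_params)
    # 2pi/3 rotation of either trimer
    g_sym = pair_energy(PairConfiguration(d, om1 + THIRD, om2), trg, ecoli_params)
    assert g_rot == pytest.approx(g, rel=1e-8)
    assert g_mir == pytest.approx(g, rel=1e-8)
    assert g_sym == pytest.approx(g, rel=1e-8)


def test_interaction_scales_quadratically_with_mismatch(ecoli_params, trg, d_face):
    cfg = PairConfiguration(d_face, *FACE_ON)
    g1 = pair_energy(cfg, trg, ecoli_params, mismatches=(0.2, 0.2))
    g2 = pair_energy(cfg, trg, ecoli_params, mismatches=(0.4, 0.4))
    assert g2 == pytest.approx(4.0 * g1, rel=1e-9)


def test_far_inclusions_do_not_interact(ecoli_params, trg):
    g = pair_energy(PairConfiguration(20.0, *FACE_ON), trg, ecoli_params)
    assert abs(g) < 0.02


def test_overlapping_configuration_rejected(ecoli_params, trg):
    with pytest.raises(ValueError, match="steric"):
        pair_energy(PairConfiguration(5.0, *FACE_ON), trg, ecoli_params)


def test_convergence_diagnostics(ecoli_params, trg, d_face):
    cfg = PairConfiguration(d_face, *FACE_ON)
    # generous tolerance passes ...
    pair_energy(cfg, trg, ecoli_params, check_convergence=True, convergence_tol=2.0)
    # ... an absurdly tight one reports non-convergence with diagnostics
    with pytest.raises(RuntimeError, match="not converged"):
        pair_energy(
            cfg, trg, ecoli_params, n_modes=6, check_convergence=True,
            convergence_tol=1e-6,
        )


def test_face_on_curve_has_three_regimes(ecoli_params, trg):
    curve = potential_curve(
        "face-on", np.arange(6.0, 14.1, 0.5), trg, ecoli_params
    )
    g = curve.energies
    assert g[0] < -15.0  # deep short-range well at the steric end point
    assert g.max() > 0.1  # intermediate repulsive barrier
    assert np.all(np.abs(g[curve.distances > 12.5]) < 0.5)  # negligible tail
    # well, barrier, tail appear in that order
    assert np.argmin(g) < np.argmax(g)


def test_magnitude_monotone_in_mismatch_and_tension(ecoli_params, trg, d_face):
    cfg = PairConfiguration(d_face, *FACE_ON)
    wells = [
        pair_energy(cfg, trg, ecoli_params, mismatches=(u, u)) for u in (0.1, 0.25, 0.4)
    ]
    assert wells[0] > wells[1] > wells[2]  # deeper with larger |mismatch|
    by_tension = [
        pair_energy(cfg, trg, ecoli_params.replace(tension=t)) for t in (0.0, 1.0, 2.0)
    ]
    assert by_tension[0] > by_tension[1] > by_tension[2]  # stronger with tension


def test_orientation_preference_switches_with_distance(ecoli_params, trg):
    """Tip-on dominates at long range; face-on is the overall optimum.

    At a fixed large separation the tip-on orientation minimises the
    energy among symmetric orientations; over all configurations (each
    orientation at its own steric-minimum distance) the face-on contact
    configuration is the global minimum.
    """
    gammas = np.linspace(0.0, math.pi / 3, 7)
    far = {
        float(g): pair_energy(
            PairConfiguration(9.5, float(g), math.pi / 3 - float(g)), trg, ecoli_params
        )
        for g in gammas
    }
    assert min(far, key=far.get) == pytest.approx(0.0)  # tip-on at long range

    path = gateway_path(trg, ecoli_params, n_points=7)
    g = path["interaction_energy_kBT"].to_numpy()
    assert np.argmin(g) == len(g) - 1  # face-on end point is the global optimum


def test_gateway_path_properties(ecoli_params, trg):
    df = gateway_path(trg, ecoli_params, n_points=7)
    assert df["delta_g_kBT"].iloc[0] == 0.0  # normalised at tip-on
    assert df["delta_g_kBT"].iloc[-1] < -10.0  # face-on end far below tip-on
    # end points are the named configurations
    assert df["omega1"].iloc[0] == pytest.approx(TIP_ON[0])
    assert df["omega1"].iloc[-1] == pytest.approx(FACE_ON[0])
    # zero mismatch flattens the whole path
    flat = gateway_path(trg, ecoli_params, n_points=5, mismatches=(0.0, 0.0))
    assert np.allclose(flat["delta_g_kBT"], 0.0, atol=1e-12)


def test_potential_curve_rejects_unknown_orientation(ecoli_params, trg):
    with pytest.raises(ValueError, match="unknown orientation"):
        potential_curve("side-on", [7.0, 8.0], trg, ecoli_params)


# --- grid oracle --------------------------------------------------------


def test_fd_single_inclusion_converges_to_closed_form(ecoli_params, trg):
    """Refinement study against the closed-form clamped cylinder energy."""
    circle = trg.with_orientation(0.0)
    from dataclasses import replace

    circle = replace(circle, threefold_amplitude=0.0)
    exact = single_inclusion_energy(ecoli_params, circle.mean_radius, 0.4)
    errs = []
    for h in (0.18, 0.12):
        e = fd_total_energy(
            ecoli_params, [circle], [(0.0, 0.0)], [0.4], grid_spacing=h
        )
        errs.append(abs(e - exact))
    assert errs[1] < errs[0]  # converging under refinement
    # first-order Richardson extrapolation lands on the closed form
    e_extrap = None
    e1 = fd_total_energy(ecoli_params, [circle], [(0.0, 0.0)], [0.4], grid_spacing=0.12)
    e2 = fd_total_energy(ecoli_params, [circle], [(0.0, 0.0)], [0.4], grid_spacing=0.18)
    e_extrap = e1 + (e1 - e2) * 0.12 / 0.06
    assert e_extrap == pytest.approx(exact, rel=0.02)


def test_fd_distant_inclusions_decouple(ecoli_params, trg):
    g = fd_oracle_energy(
        PairConfiguration(18.0, *FACE_ON), trg, ecoli_params, grid_spacing=0.15
    )
    assert abs(g) < 0.3


def test_fd_matches_series_at_contact(ecoli_params, trg, d_face):
    cfg = PairConfiguration(d_face, *FACE_ON)
    g_series = pair_energy(cfg, trg, ecoli_params)
    g_fd = fd_oracle_energy(
        cfg, trg, ecoli_params, grid_spacing=0.12, richardson=True
    )
    assert g_fd == pytest.approx(g_series, rel=0.10)


def test_fd_rejects_coarse_grids(ecoli_params, trg):
    with pytest.raises(ValueError, match="resolve the decay length"):
        fd_oracle_energy(
            PairConfiguration(9.0, *FACE_ON), trg, ecoli_params, grid_spacing=0.5
        )
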