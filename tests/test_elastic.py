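"""Characteristic roots, single-inclusion solutions and energy quadrature."""

import numpy as np
import pytest

from memrec import (
    MembraneParams,
    characteristic_roots,
    single_inclusion_profile,
    single_inclusion_energy,
    deformation_energy,
)


PARAM_SETS = [
    MembraneParams(),
    MembraneParams(tension=1.5),
    MembraneParams(bending_modulus=10.0, thickness_stiffness=40.0, monolayer_thickness=1.6),
    # beyond the degeneracy tension: two real roots
    MembraneParams(tension=60.0),
]


@pytest.mark.parametrize("params", PARAM_SETS)
def test_roots_satisfy_characteristic_polynomial(params):
    roots = characteristic_roots(params)
    kb, beta = params.bending_modulus, params.restoring_coefficient
    for nu in (roots.root_plus, roots.root_minus):
        resid = kb * nu**2 - params.tension * nu + beta
        scale = abs(kb * nu**2) + abs(params.tension * nu) + beta
        assert abs(resid) / scale < 1e-12


def test_zero_tension_roots_are_conjugate_pair():
    roots = characteristic_roots(MembraneParams(tension=0.0))
    assert roots.root_plus == pytest.approx(np.conj(roots.root_minus))
    assert roots.root_plus.real == pytest.approx(0.0, abs=1e-14)
    assert not roots.degenerate


def test_decay_length_continuous_in_tension():
    taus = np.linspace(0.0, 3.0, 61)
    lengths = [characteristic_roots(MembraneParams(tension=t)).decay_length for t in taus]
    steps = np.abs(np.diff(lengths))
    assert steps.max() < 0.02  # no jumps on a fine tension grid


def test_degenerate_roots_flagged():
    p = MembraneParams()
    tau_c = 2.0 * np.sqrt(p.bending_modulus * p.thickness_stiffness) / p.monolayer_thickness
    roots = characteristic_roots(p.replace(tension=tau_c))
    assert roots.degenerate
    assert not characteristic_roots(p.replace(tension=0.9 * tau_c)).degenerate


def test_decay_length_matches_arbitrary_precision_oracle(ecoli_params):
    """Closed form evaluated independently at 50-digit precision."""
    import mpmath

    mpmath.mp.dps = 50
    p = ecoli_params
    kb = mpmath.mpf(p.bending_modulus)
    beta = mpmath.mpf(p.thickness_stiffness) / mpmath.mpf(p.monolayer_thickness) ** 2
    tau = mpmath.mpf(p.tension)
    nu = (tau + mpmath.sqrt(tau**2 - 4 * kb * beta)) / (2 * kb)
    k = mpmath.sqrt(nu)
    if mpmath.re(k) < 0:
        k = -k
    expected = float(1 / mpmath.re(k))
    assert characteristic_roots(p).decay_length == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("slope_bc", ["clamped", "free"])
def test_profile_matches_boundary_value(ecoli_params, slope_bc):
    prof = single_inclusion_profile(ecoli_params, 3.1, 0.4, slope_bc=slope_bc)
    u_eff = ecoli_params.effective_mismatch(0.4)
    assert prof.radial(3.1) == pytest.approx(u_eff, abs=1e-10)
    assert abs(prof.radial(40.0)) < 1e-8  # decays to zero


def test_zero_mismatch_null(ecoli_params):
    prof = single_inclusion_profile(ecoli_params, 3.1, 0.0)
    r = np.linspace(3.1, 20.0, 50)
    assert np.allclose(prof.radial(r), 0.0, atol=1e-14)
    assert single_inclusion_energy(ecoli_params, 3.1, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_zero_tension_profile_overshoots(ecoli_params):
    """Complex roots produce a compression zone: the profile changes sign."""
    prof = single_inclusion_profile(ecoli_params, 3.1, 0.4)
    r = np.linspace(3.1, 25.0, 4000)
    u = prof.radial(r)
    assert np.sum(np.diff(np.sign(u[np.abs(u) > 1e-13])) != 0) >= 1


@pytest.mark.parametrize("slope_bc", ["clamped", "free"])
def test_quadrature_agrees_with_closed_form(ecoli_params, slope_bc):
    """Grid quadrature of the energy density vs the boundary-term closed form."""
    closed = single_inclusion_energy(ecoli_params, 3.1, 0.4, slope_bc=slope_bc)
    prof = single_inclusion_profile(ecoli_params, 3.1, 0.4, slope_bc=slope_bc)
    quad = deformation_energy(
        prof,
        ecoli_params,
        (-13.0, 13.0, -13.0, 13.0),
        spacing=0.02,
        exclude=lambda X, Y: np.hypot(X, Y) < 3.1,
        refine=True,
    )
    assert quad == pytest.approx(closed, rel=0.005)


def test_quadrature_reports_too_small_domain(ecoli_params):
    prof = single_inclusion_profile(ecoli_params, 3.1, 0.4)
    with pytest.raises(ValueError, match="domain too small"):
        deformation_energy(
            prof, ecoli_params, (-5.0, 5.0, -5.0, 5.0), spacing=0.05,
            exclude=lambda X, Y: np.hypot(X, Y) < 3.1,
        )


def test_energy_scales_quadratically_with_mismatch(ecoli_params):
    e1 = single_inclusion_energy(ecoli_params, 3.1, 0.2)
    e2 = single_inclusion_energy(ecoli_params, 3.1, 0.4)
    assert e2 == pytest.approx(4.0 * e1, rel=1e-10)
    assert single_inclusion_energy(ecoli_params, 3.1, 0.3) > e1 > 0


def test_tension_increases_energy_at_positive_mismatch(ecoli_params):
    energies = [
        single_inclusion_energy(ecoli_params.replace(tension=t), 3.1, 0.4)
        for t in (0.0, 0.5, 1.0, 2.0)
    ]
    assert all(b > a for a, b in zip(energies, energies[1:]))


def test_invalid_inputs_rejected(ecoli_params):
    with pytest.raises(ValueError):
        single_inclusion_energy(ecoli_params, -1.0, 0.4)
    with pytest.raises(ValueError):
        MembraneParams(bending_modulus=-5.0)
    with pytest.raises(ValueError):
        MembraneParams(tension=-0.1)


def test_degenerate_closed_form_is_limit_of_neighbours():
    """The confluent solution family continuously extends the generic one."""
    p = MembraneParams()
    tau_c = 2.0 * np.sqrt(p.bending_modulus * p.thickness_stiffness) / p.monolayer_thickness
    e_at = single_inclusion_energy(p.replace(tension=tau_c), 3.1, 0.4)
    e_below = single_inclusion_energy(p.replace(tension=tau_c * (1 - 1e-4)), 3.1, 0.4)
    e_above = single_inclusion_energy(p.replace(tension=tau_c * (1 + 1e-4)), 3.1, 0.4)
    assert e_at == pytest.approx(0.5 * (e_below + e_above), rel=1e-3)
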