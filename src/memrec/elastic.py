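"""Bilayer thickness-deformation elasticity.

The lipid bilayer is described in the Monge gauge by the deviation
``u(x, y)`` of the leaflet hydrophobic half-thickness from its unperturbed
value ``a``.  The elastic energy of a thickness-deformation field is

.. math::

    G[u] = \\int \\mathrm{d}x\\,\\mathrm{d}y \\left[
        \\frac{K_b}{2}\\,(\\nabla^2 u)^2
        + \\frac{K_t}{2}\\,\\Bigl(\\frac{u}{a}\\Bigr)^2
        + \\frac{\\tau}{2}\\,(\\nabla u)^2
        + \\tau\\,\\frac{u}{a}
    \\right],

with ``K_b`` the bilayer bending modulus (k_BT), ``K_t`` the stiffness of
thickness deformations (k_BT/nm^2, of the order of the bilayer
area-stretch modulus), and ``tau`` the membrane tension (k_BT/nm^2).  The
quadratic terms penalise bending of the hydrophobic interfaces and
compression/expansion of the lipid tails; the two tension terms account
for the work done against tension by membrane undulations and, through the
linear coupling ``tau u/a``, for the thinning of the bilayer under tension
at conserved lipid volume.

Conventions (used consistently throughout the package):

* ``u`` is the *half*-thickness (per-leaflet) deviation; the functional
  above is the energy of the whole bilayer, not of one monolayer.
* All energies are in units of k_BT, lengths in nm, tension in k_BT/nm^2.
* Energies are measured relative to the flat membrane at the same tension.
  The tension-thinned equilibrium state is ``u_eq = -tau a / K_t``; because
  the linear tension term is exactly stationary there, the energy relative
  to that state is the pure quadratic form in ``h = u - u_eq``, and a
  protein with hydrophobic mismatch ``U0 = w - a`` imposes the *effective*
  boundary mismatch ``U0 + tau a / K_t``.  At zero tension a protein whose
  hydrophobic thickness matches the bilayer deforms nothing and all
  energies vanish identically.

Minimisers of the quadratic form satisfy the Euler-Lagrange equation
``K_b lap^2 h - tau lap h + (K_t/a^2) h = 0``.  Exponential solutions with
``lap h = nu h`` require ``K_b nu^2 - tau nu + K_t/a^2 = 0``; the two roots
``nu±`` define the decaying radial solution families ``K_n(sqrt(nu±) r)``.
Below the degeneracy tension the roots are a complex-conjugate pair, so
radial profiles decay with a damped oscillation ("overshoot").
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.special import kv


__all__ = [
    "MembraneParams",
    "DecayRoots",
    "characteristic_roots",
    "DeformationField",
    "RadialDeformationField",
    "GridDeformationField",
    "single_inclusion_profile",
    "single_inclusion_energy",
    "deformation_energy",
]


@dataclass(frozen=True)
class MembraneParams:
    """Elastic parameters of the lipid bilayer.

    Parameters
    ----------
    bending_modulus : float
        Bilayer bending rigidity ``K_b`` in k_BT.
    thickness_stiffness : float
        Stiffness ``K_t`` associated with thickness deformations, in
        k_BT/nm^2 (per-bilayer convention, see module docstring).
    tension : float
        Membrane tension ``tau`` in k_BT/nm^2.
    monolayer_thickness : float
        One-half of the hydrophobic thickness of the unperturbed lipid
        bilayer, ``a``, in nm.
    """

    bending_modulus: float = 20.0
    thickness_stiffness: float = 60.0
    tension: float = 0.0
    monolayer_thickness: float = 1.4

    def __post_init__(self) -> None:
        if self.bending_modulus <= 0:
            raise ValueError("bending_modulus must be positive")
        if self.thickness_stiffness <= 0:
            raise ValueError("thickness_stiffness must be positive")
        if self.tension < 0:
            raise ValueError("tension must be non-negative")
        if self.monolayer_thickness <= 0:
            raise ValueError("monolayer_thickness must be positive")

    @property
    def restoring_coefficient(self) -> float:
        """``beta = K_t / a^2`` in k_BT/nm^4 (coefficient of ``h^2/2``)."""
        return self.thickness_stiffness / self.monolayer_thickness**2

    @property
    def equilibrium_shift(self) -> float:
        """Tension-induced equilibrium thinning ``u_eq = -tau a / K_t`` (nm)."""
        return -self.tension * self.monolayer_thickness / self.thickness_stiffness

    def effective_mismatch(self, mismatch: float) -> float:
        """Boundary value of ``h = u - u_eq`` for a protein mismatch ``w - a``."""
        return mismatch - self.equilibrium_shift

    def replace(self, **kwargs) -> "MembraneParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class DecayRoots:
    """Roots ``nu±`` of the characteristic polynomial and the decay length.

    ``K_b nu^2 - tau nu + K_t/a^2 = 0``.  ``decay_length`` is
    ``1/Re(sqrt(nu))`` in nm, the characteristic length over which
    thickness deformations relax around an inclusion.
    """

    root_plus: complex
    root_minus: complex
    decay_length: float
    degenerate: bool = False

    @property
    def wavenumbers(self) -> tuple[complex, complex]:
        """``k± = sqrt(nu±)`` with positive real part (decaying branch)."""
        ks = []
        for nu in (self.root_plus, self.root_minus):
            k = complex(np.sqrt(complex(nu)))
            if k.real < 0:
                k = -k
            ks.append(k)
        return ks[0], ks[1]


def characteristic_roots(
    params: MembraneParams, *, degeneracy_rtol: float = 1e-9
) -> DecayRoots:
    """Roots of the Euler-Lagrange characteristic polynomial.

    At zero tension the roots are the purely imaginary conjugate pair
    ``nu± = ± i sqrt(K_t / K_b) / a``; the resulting complex wavenumber
    produces exponentially damped oscillatory profiles (thickness
    overshoot).  With growing tension the pair acquires a real part and,
    beyond the (unphysically large) degeneracy tension
    ``tau_c = 2 sqrt(K_b K_t) / a``, splits into two real roots.

    Exactly repeated roots (relative discriminant below
    ``degeneracy_rtol``) are flagged via ``DecayRoots.degenerate``; the
    closed-form single-inclusion solution then switches to the limiting
    confluent solution family.
    """
    kb = params.bending_modulus
    beta = params.restoring_coefficient
    tau = params.tension
    disc = complex(tau * tau - 4.0 * kb * beta)
    sq = np.sqrt(disc)
    nu_p = (tau + sq) / (2.0 * kb)
    nu_m = (tau - sq) / (2.0 * kb)
    degenerate = abs(disc) <= degeneracy_rtol * (4.0 * kb * beta)
    k_p = complex(np.sqrt(nu_p))
    if k_p.real < 0:
        k_p = -k_p
    if k_p.real == 0:
        raise ValueError("non-decaying characteristic root; invalid parameters")
    return DecayRoots(
        root_plus=complex(nu_p),
        root_minus=complex(nu_m),
        decay_length=1.0 / k_p.real,
        degenerate=degenerate,
    )


class DeformationField:
    """Interface of an evaluatable thickness-deformation field ``h(x, y)``.

    ``h`` is measured relative to the tension-thinned flat state (see
    module docstring); it equals the effective hydrophobic mismatch on
    inclusion boundaries and decays to zero far from all inclusions.
    """

    def evaluate(self, x, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, y):
        return self.evaluate(x, y)


@dataclass
class RadialDeformationField(DeformationField):
    """Axisymmetric series field around a single circular inclusion.

    ``h(r) = Re[ c+ K_0(k+ r) + c- K_0(k- r) ]`` for distinct roots; in the
    degenerate case the second family is the confluent limit
    ``d/dnu K_0(sqrt(nu) r) = (r / 2k) K_0'(k r)``.
    """

    radius: float
    coefficients: tuple[complex, complex]
    roots: DecayRoots

    def radial(self, r):
        r = np.asarray(r, dtype=float)
        kp, km = self.roots.wavenumbers
        cp, cm = self.coefficients
        with np.errstate(invalid="ignore"):
            if not self.roots.degenerate:
                vals = cp * kv(0, kp * r) + cm * kv(0, km * r)
            else:
                vals = cp * kv(0, kp * r) + cm * (-r / (2.0 * kp)) * kv(1, kp * r)
        return np.real(vals)

    def radial_derivative(self, r):
        r = np.asarray(r, dtype=float)
        kp, km = self.roots.wavenumbers
        cp, cm = self.coefficients
        if not self.roots.degenerate:
            vals = -cp * kp * kv(1, kp * r) - cm * km * kv(1, km * r)
        else:
            # d/dr [ -r/(2k) K_1(k r) ] = -1/(2k) K_1 - (r/2) K_1'
            k1 = kv(1, kp * r)
            dk1 = -0.5 * (kv(0, kp * r) + kv(2, kp * r))
            vals = -cp * kp * k1 + cm * (-(k1 / (2.0 * kp)) - (r / 2.0) * dk1)
        return np.real(vals)

    def evaluate(self, x, y):
        r = np.hypot(np.asarray(x, float), np.asarray(y, float))
        return self.radial(np.maximum(r, self.radius))


@dataclass
class GridDeformationField(DeformationField):
    """Field sampled on a regular grid; bilinear interpolation off-node."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # shape (len(x), len(y))

    def evaluate(self, x, y):
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.x, self.y), self.values, bounds_error=False, fill_value=0.0
        )
        pts = np.stack(np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float)), axis=-1)
        return interp(pts)

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])


def _single_solution(
    params: MembraneParams, radius: float, boundary_value: float, slope_bc: str
) -> RadialDeformationField:
    """Solve the axisymmetric two-family boundary-value problem."""
    roots = characteristic_roots(params)
    kp, km = roots.wavenumbers
    nup, num = roots.root_plus, roots.root_minus
    if not roots.degenerate:
        row_val = [kv(0, kp * radius), kv(0, km * radius)]
        if slope_bc == "clamped":
            row2 = [-kp * kv(1, kp * radius), -km * kv(1, km * radius)]
        elif slope_bc == "free":
            # natural condition from free boundary slope: lap h = 0 on the edge
            row2 = [nup * kv(0, kp * radius), num * kv(0, km * radius)]
        else:
            raise ValueError(f"unknown slope_bc {slope_bc!r}")
    else:
        # confluent family psi2 = d/dnu K_0(sqrt(nu) r) = -(r/2k) K_1(k r)
        psi2 = -(radius / (2.0 * kp)) * kv(1, kp * radius)
        dpsi2 = -(kv(1, kp * radius) / (2.0 * kp)) - (radius / 2.0) * (
            -0.5 * (kv(0, kp * radius) + kv(2, kp * radius))
        )
        row_val = [kv(0, kp * radius), psi2]
        if slope_bc == "clamped":
            row2 = [-kp * kv(1, kp * radius), dpsi2]
        elif slope_bc == "free":
            # lap psi2 = psi1 + nu psi2
            row2 = [nup * kv(0, kp * radius), kv(0, kp * radius) + nup * psi2]
        else:
            raise ValueError(f"unknown slope_bc {slope_bc!r}")
    mat = np.array([row_val, row2], dtype=complex)
    rhs = np.array([boundary_value, 0.0], dtype=complex)
    cp, cm = np.linalg.solve(mat, rhs)
    return RadialDeformationField(radius=radius, coefficients=(cp, cm), roots=roots)


def single_inclusion_profile(
    params: MembraneParams,
    radius: float,
    mismatch: float,
    *,
    slope_bc: str = "clamped",
) -> RadialDeformationField:
    """Thickness-deformation profile around an isolated cylindrical inclusion.

    The field equals the effective hydrophobic mismatch at ``r = radius``
    and decays (with overshoot, at sub-degenerate tension) to zero.  The
    boundary slope is either clamped to zero (default) or left free (the
    energy-minimising natural condition ``lap h = 0``).

    Parameters
    ----------
    params : MembraneParams
    radius : float
        Inclusion radius in nm; must be positive.
    mismatch : float
        Protein-bilayer hydrophobic half-thickness mismatch ``w - a`` (nm).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    u_eff = params.effective_mismatch(mismatch)
    return _single_solution(params, radius, u_eff, slope_bc)


def single_inclusion_energy(
    params: MembraneParams,
    radius: float,
    mismatch: float,
    *,
    slope_bc: str = "clamped",
) -> float:
    """Closed-form deformation energy (k_BT) of an isolated cylinder.

    Evaluated from the boundary terms of the quadratic form,

    ``E = -pi R [ K_b (lap h h' - h lap h') + tau h h' ]`` at ``r = R``,

    which is exact for solutions of the Euler-Lagrange equation.  The
    energy is a positive-definite quadratic form in the effective
    mismatch; at fixed positive mismatch it increases with tension both
    through the effective mismatch and through the tension term itself.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sol = single_inclusion_profile(params, radius, mismatch, slope_bc=slope_bc)
    return _boundary_energy_radial(sol, params)


def _boundary_energy_radial(sol: RadialDeformationField, params: MembraneParams) -> float:
    R = sol.radius
    kp, km = sol.roots.wavenumbers
    nup, num = sol.roots.root_plus, sol.roots.root_minus
    cp, cm = sol.coefficients
    if not sol.roots.degenerate:
        h = cp * kv(0, kp * R) + cm * kv(0, km * R)
        hr = -cp * kp * kv(1, kp * R) - cm * km * kv(1, km * R)
        lap = cp * nup * kv(0, kp * R) + cm * num * kv(0, km * R)
        lapr = -cp * nup * kp * kv(1, kp * R) - cm * num * km * kv(1, km * R)
    else:
        psi1, psi1r = kv(0, kp * R), -kp * kv(1, kp * R)
        psi2 = -(R / (2.0 * kp)) * kv(1, kp * R)
        psi2r = -(kv(1, kp * R) / (2.0 * kp)) - (R / 2.0) * (
            -0.5 * (kv(0, kp * R) + kv(2, kp * R))
        )
        h = cp * psi1 + cm * psi2
        hr = cp * psi1r + cm * psi2r
        lap = cp * nup * psi1 + cm * (psi1 + nup * psi2)
        lapr = cp * nup * psi1r + cm * (psi1r + nup * psi2r)
    kb, tau = params.bending_modulus, params.tension
    # outward normal of the membrane domain points toward the inclusion (-r)
    integrand = kb * (lap * (-hr) - h * (-lapr)) + tau * h * (-hr)
    return float(np.real(0.5 * 2.0 * np.pi * R * integrand))


def deformation_energy(
    field: DeformationField,
    params: MembraneParams,
    domain: tuple[float, float, float, float],
    *,
    spacing: float = 0.05,
    exclude=None,
    boundary_tolerance: float = 1e-3,
    refine: bool = False,
) -> float:
    """Numerical quadrature of the thickness-deformation energy density.

    Samples ``field`` on a regular grid over ``domain = (x0, x1, y0, y1)``,
    forms the quadratic energy density with central finite differences and
    integrates.  Grid cells for which ``exclude(x, y)`` is true (e.g.
    inclusion interiors) are omitted.  This is deliberately independent of
    the closed-form boundary-term energies and serves as their check.

    The leading quadrature error is linear in the spacing (one-cell rim
    around excluded boundaries); ``refine=True`` removes it by linear
    extrapolation from ``spacing`` and ``1.5 * spacing``.

    Raises
    ------
    ValueError
        If the field has not decayed at the domain edge (relative boundary
        magnitude above ``boundary_tolerance``), i.e. the domain is too
        small for the quadrature to be trusted.
    """
    if refine:
        e1 = deformation_energy(
            field, params, domain, spacing=spacing, exclude=exclude,
            boundary_tolerance=boundary_tolerance,
        )
        e2 = deformation_energy(
            field, params, domain, spacing=1.5 * spacing, exclude=exclude,
            boundary_tolerance=boundary_tolerance,
        )
        return e1 + (e1 - e2) * spacing / (0.5 * spacing)
    x0, x1, y0, y1 = domain
    x = np.arange(x0, x1 + spacing / 2, spacing)
    y = np.arange(y0, y1 + spacing / 2, spacing)
    X, Y = np.meshgrid(x, y, indexing="ij")
    H = np.asarray(field.evaluate(X, Y), dtype=float)

    interior = np.ones_like(H, dtype=bool)
    if exclude is not None:
        interior = ~np.asarray(exclude(X, Y), dtype=bool)

    edge = np.concatenate([H[0, :], H[-1, :], H[:, 0], H[:, -1]])
    scale = np.max(np.abs(H)) or 1.0
    flux = float(np.max(np.abs(edge)) / scale)
    if flux > boundary_tolerance:
        raise ValueError(
            f"domain too small: relative boundary magnitude {flux:.2e} exceeds "
            f"{boundary_tolerance:.2e}"
        )

    hx = np.gradient(H, spacing, axis=0)
    hy = np.gradient(H, spacing, axis=1)
    lap = (
        np.gradient(np.gradient(H, spacing, axis=0), spacing, axis=0)
        + np.gradient(np.gradient(H, spacing, axis=1), spacing, axis=1)
    )
    dens = (
        0.5 * params.bending_modulus * lap**2
        + 0.5 * params.restoring_coefficient * H**2
        + 0.5 * params.tension * (hx**2 + hy**2)
    )
    # drop a one-cell rim around excluded regions where FD stencils straddle
    if exclude is not None:
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(interior, iterations=2, border_value=1)
    dens = np.where(interior, dens, 0.0)
    return float(np.sum(dens) * spacing**2)
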