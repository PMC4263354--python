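"""Angular-harmonic series solutions for one or more membrane inclusions.

The thickness-deformation field outside a set of inclusions is expanded in
decaying cylindrical harmonics about each inclusion centre,

    h(x, y) = sum_i sum_s sum_n  c_{i,s,n}  K_n(k_s rho_i) e^{i n theta_i},

with one radial family per characteristic root (``k_s = sqrt(nu_s)``).
Below the degeneracy tension the two roots are complex conjugates and the
real solution space is spanned by the real and imaginary parts of the
``k_+`` family alone; above it both real families enter.  Boundary
conditions — the effective hydrophobic mismatch for the field value, plus
either a clamped (zero) boundary slope or the energy-minimising natural
condition ``lap h = 0`` — are imposed on the *exact* perturbed boundary
curves by least-squares collocation.  Because every basis function solves
the Euler-Lagrange equation exactly, the elastic energy reduces to
boundary integrals which are evaluated by periodic trapezoidal quadrature
(spectrally accurate in the boundary parametrisation).

This module is internal machinery; use :mod:`memrec.pair` for the public
pair-potential API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kv

from .elastic import MembraneParams, DeformationField, characteristic_roots
from .geometry import InclusionShape


__all__ = ["SeriesSolution", "solve_inclusions"]


def _families(params: MembraneParams):
    roots = characteristic_roots(params)
    if roots.degenerate:
        raise NotImplementedError(
            "collocation solver does not support exactly repeated characteristic "
            "roots (tension at the degeneracy point); perturb the tension or use "
            "the closed-form single-inclusion solution"
        )
    kp, km = roots.wavenumbers
    nup, num = roots.root_plus, roots.root_minus
    conjugate = abs(nup.conjugate() - num) <= 1e-12 * abs(nup)
    if conjugate:
        return roots, [(kp, nup, ("re", "im"))]
    return roots, [(kp, nup, ("re",)), (km, num, ("re",))]


def _block_columns(pts, center, families, n_modes, *, derivatives=False):
    """Columns (value, lap[, grad, lapgrad]) of the real basis of one inclusion."""
    x = pts[:, 0] - center[0]
    y = pts[:, 1] - center[1]
    rho = np.hypot(x, y)
    th = np.arctan2(y, x)
    ct, st = np.cos(th), np.sin(th)
    V, L, GX, GY, LGX, LGY = [], [], [], [], [], []
    orders = np.arange(n_modes + 2)
    for k, nu, parts in families:
        # K_n(k rho) for n = 0..N+1 in one broadcast call
        K = kv(orders[:, None], k * rho[None, :])
        for n in range(n_modes + 1):
            psi = K[n]
            dpsi = -0.5 * k * (K[n - 1] + K[n + 1]) if n >= 1 else -k * K[1]
            for sgn in ((1,) if n == 0 else (1, -1)):
                e = np.exp(1j * sgn * n * th)
                f = psi * e
                for part in (np.real, np.imag) if parts == ("re", "im") else (np.real,):
                    V.append(part(f))
                    L.append(part(nu * f))
                    if derivatives:
                        fr = dpsi * e
                        ft = 1j * sgn * n * psi * e
                        gx = fr * ct - ft * st / rho
                        gy = fr * st + ft * ct / rho
                        GX.append(part(gx))
                        GY.append(part(gy))
                        LGX.append(part(nu * gx))
                        LGY.append(part(nu * gy))
    out = [np.array(V).T, np.array(L).T]
    if derivatives:
        out += [np.array(GX).T, np.array(GY).T, np.array(LGX).T, np.array(LGY).T]
    return out


def _boundary_frame(shape: InclusionShape, center, m: int):
    """Midpoint nodes, outward curve normals and arc elements of a boundary."""
    th = (np.arange(m) + 0.5) * 2.0 * np.pi / m
    r = shape.boundary_radius(th)
    drdth = (
        -3.0
        * shape.mean_radius
        * shape.threefold_amplitude
        * np.sin(3.0 * (th - shape.orientation))
    )
    x = center[0] + r * np.cos(th)
    y = center[1] + r * np.sin(th)
    tx = drdth * np.cos(th) - r * np.sin(th)
    ty = drdth * np.sin(th) + r * np.cos(th)
    norm = np.hypot(tx, ty)
    ds = norm * 2.0 * np.pi / m
    nx, ny = ty / norm, -tx / norm
    # orient outward (away from the centre)
    flip = nx * (x - center[0]) + ny * (y - center[1]) < 0
    nx = np.where(flip, -nx, nx)
    ny = np.where(flip, -ny, ny)
    return np.column_stack([x, y]), nx, ny, ds


@dataclass
class SeriesSolution:
    """A solved multi-inclusion boundary-value problem."""

    params: MembraneParams
    shapes: tuple[InclusionShape, ...]
    centers: np.ndarray
    boundary_values: tuple[float, ...]
    n_modes: int
    slope_bc: str
    coefficients: np.ndarray
    residual: float

    def _blocks(self, pts, derivatives=False):
        _, families = _families(self.params)
        ncols = None
        tot = None
        off = 0
        for shape, center in zip(self.shapes, self.centers):
            blocks = _block_columns(
                pts, center, families, self.n_modes, derivatives=derivatives
            )
            ncols = blocks[0].shape[1]
            c = self.coefficients[off : off + ncols]
            contrib = tuple(b @ c for b in blocks)
            tot = contrib if tot is None else tuple(t + b for t, b in zip(tot, contrib))
            off += ncols
        return tot

    def evaluate(self, x, y):
        """Field h at points (x, y); inclusion interiors return the boundary value."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shp = np.broadcast_shapes(x.shape, y.shape)
        X = np.broadcast_to(x, shp).ravel()
        Y = np.broadcast_to(y, shp).ravel()
        out = np.empty(X.size)
        inside_any = np.zeros(X.size, dtype=bool)
        for shape, center, u in zip(self.shapes, self.centers, self.boundary_values):
            rho = np.hypot(X - center[0], Y - center[1])
            th = np.arctan2(Y - center[1], X - center[0])
            inside = rho <= shape.boundary_radius(th)
            out[inside] = u
            inside_any |= inside
        if np.any(~inside_any):
            pts = np.column_stack([X[~inside_any], Y[~inside_any]])
            out[~inside_any] = self._blocks(pts)[0]
        return out.reshape(shp)

    def field(self) -> DeformationField:
        sol = self

        class _Adapter(DeformationField):
            def evaluate(self, x, y):
                return sol.evaluate(x, y)

        return _Adapter()

    def energy(self, quadrature_points: int | None = None) -> float:
        """Elastic energy (k_BT) from exact boundary-term integrals."""
        m = quadrature_points or max(256, 16 * (self.n_modes + 1))
        kb, tau = self.params.bending_modulus, self.params.tension
        total = 0.0
        for shape, center in zip(self.shapes, self.centers):
            pts, nx, ny, ds = _boundary_frame(shape, center, m)
            h, lap, gx, gy, lgx, lgy = self._blocks(pts, derivatives=True)
            dn_h = -(gx * nx + gy * ny)  # membrane-outward normal points inward
            dn_lap = -(lgx * nx + lgy * ny)
            integrand = kb * (lap * dn_h - h * dn_lap) + tau * h * dn_h
            total += 0.5 * float(np.sum(integrand * ds))
        return total


def solve_inclusions(
    params: MembraneParams,
    shapes,
    centers,
    mismatches,
    *,
    n_modes: int = 12,
    slope_bc: str = "clamped",
    collocation_factor: int = 8,
) -> SeriesSolution:
    """Least-squares collocation solve for one or more inclusions.

    Parameters
    ----------
    mismatches : sequence of float
        Bare hydrophobic mismatches ``w_i - a``; the tension-induced
        effective shift is applied internally.
    n_modes : int
        Angular-harmonic truncation order per inclusion per root family.
    slope_bc : {"clamped", "free"}
        Clamp the boundary slope to zero (default) or leave it free
        (natural condition ``lap h = 0``).
    """
    if slope_bc not in ("clamped", "free"):
        raise ValueError(f"unknown slope_bc {slope_bc!r}")
    if n_modes < 0:
        raise ValueError("n_modes must be >= 0")
    for shape in shapes:
        if abs(shape.threefold_amplitude) > 0.3:
            import warnings

            warnings.warn(
                f"three-fold amplitude {shape.threefold_amplitude:.2f} is outside "
                "the weakly-perturbed regime; raise n_modes and check convergence",
                stacklevel=2,
            )
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    shapes = tuple(shapes)
    u_eff = tuple(params.effective_mismatch(float(u)) for u in mismatches)
    roots, families = _families(params)
    m = max(32, collocation_factor * (n_modes + 1))

    frames = [
        _boundary_frame(shape, center, m) for shape, center in zip(shapes, centers)
    ]
    pts = np.vstack([f[0] for f in frames])
    nx = np.concatenate([f[1] for f in frames])
    ny = np.concatenate([f[2] for f in frames])

    Vb, Sb = [], []
    for center in centers:
        v, lap, gx, gy, _, _ = _block_columns(
            pts, center, families, n_modes, derivatives=True
        )
        Vb.append(v)
        if slope_bc == "clamped":
            Sb.append(gx * nx[:, None] + gy * ny[:, None])
        else:
            Sb.append(lap)
    V = np.hstack(Vb)
    S = np.hstack(Sb)
    # balance the two condition types
    kscale = abs(roots.wavenumbers[0])
    S = S / (kscale if slope_bc == "clamped" else kscale**2)
    A = np.vstack([V, S])
    rhs = np.concatenate(
        [np.concatenate([np.full(m, u) for u in u_eff]), np.zeros(len(shapes) * m)]
    )
    col = np.max(np.abs(A), axis=0)
    col[col == 0] = 1.0
    coef, *_ = np.linalg.lstsq(A / col, rhs, rcond=None)
    coef = coef / col
    scale = max(max(abs(u) for u in u_eff), 1e-30)
    residual = float(np.max(np.abs(A @ coef - rhs)) / scale)
    return SeriesSolution(
        params=params,
        shapes=shapes,
        centers=centers,
        boundary_values=u_eff,
        n_modes=n_modes,
        slope_bc=slope_bc,
        coefficients=coef,
        residual=residual,
    )
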