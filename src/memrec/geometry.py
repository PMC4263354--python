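"""Trimer cross-section geometry, steric constraints and lattice generators.

A chemoreceptor trimer-of-dimers is modelled as a rigid, weakly perturbed
cylindrical membrane inclusion with three-fold symmetric cross-section

    r(theta) = R [1 + eps cos 3(theta - omega)],

where ``R`` is the mean radius, ``eps`` the fractional three-fold boundary
perturbation and ``omega`` the in-plane orientation.  "Tips" are the three
boundary maxima (theta = omega + 2 pi k / 3) and "faces" the three minima
between them.  With the bond between two trimers along +x, the tip-on pair
points tips at each other (omega1 = 0, omega2 = pi/3) and the face-on pair
confronts faces (omega1 = pi/3, omega2 = 0); both are mirror-symmetric
about the bond axis and map onto each other under the perpendicular-
bisector reflection.

Three lattice architectures are generated: the close-packed hexagonal
lattice (six nearest neighbours, uniform trimer orientation) and the two
honeycomb lattices (three nearest neighbours) in which every bond is in
the face-on or in the tip-on configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist


__all__ = [
    "InclusionShape",
    "PairConfiguration",
    "LatticeSpec",
    "LatticeSite",
    "TIP_ON",
    "FACE_ON",
    "HEXAGONAL_UNIFORM_ORIENTATION",
    "boundary_radius",
    "min_center_distance",
    "lattice_sites",
    "area_per_trimer",
]


#: Uniform trimer orientation used in the hexagonal lattice: tips bisect the
#: bond directions, so all six bonds are equivalent and mirror-symmetric.
HEXAGONAL_UNIFORM_ORIENTATION = math.pi / 6


@dataclass(frozen=True)
class InclusionShape:
    """Cross-section of a trimer in the membrane plane."""

    mean_radius: float = 3.1
    threefold_amplitude: float = 0.2
    orientation: float = 0.0
    hydrophobic_half_thickness: float = 1.8

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if not -1.0 < self.threefold_amplitude < 1.0:
            raise ValueError("threefold_amplitude must lie in (-1, 1)")
        if self.hydrophobic_half_thickness <= 0:
            raise ValueError("hydrophobic_half_thickness must be positive")

    def boundary_radius(self, angle):
        """Boundary radius r(theta) in nm; exactly 2 pi/3 periodic."""
        angle = np.asarray(angle, dtype=float)
        return self.mean_radius * (
            1.0 + self.threefold_amplitude * np.cos(3.0 * (angle - self.orientation))
        )

    def boundary_points(self, n: int = 720, center=(0.0, 0.0)):
        """Sample the boundary curve as an (n, 2) array of (x, y)."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = self.boundary_radius(theta)
        return np.column_stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
        )

    def mismatch(self, params) -> float:
        """Hydrophobic half-thickness mismatch w - a in nm."""
        return self.hydrophobic_half_thickness - params.monolayer_thickness

    def with_orientation(self, omega: float) -> "InclusionShape":
        return replace(self, orientation=omega)

    @property
    def max_radius(self) -> float:
        return self.mean_radius * (1.0 + abs(self.threefold_amplitude))


def boundary_radius(shape: InclusionShape, angle):
    """Functional alias for :meth:`InclusionShape.boundary_radius`."""
    return shape.boundary_radius(angle)


@dataclass(frozen=True)
class PairConfiguration:
    """Two trimers at centre distance ``d`` with orientations (omega1, omega2).

    The bond is taken along +x with trimer 1 at the origin.
    """

    center_distance: float
    orientation_1: float = 0.0
    orientation_2: float = math.pi / 3

    @classmethod
    def tip_on(cls, d: float) -> "PairConfiguration":
        return cls(d, 0.0, math.pi / 3)

    @classmethod
    def face_on(cls, d: float) -> "PairConfiguration":
        return cls(d, math.pi / 3, 0.0)

    @property
    def centers(self):
        return np.array([[0.0, 0.0], [self.center_distance, 0.0]])

    @property
    def orientations(self):
        return (self.orientation_1, self.orientation_2)


TIP_ON = (0.0, math.pi / 3)
FACE_ON = (math.pi / 3, 0.0)


def _boundary_gap(
    d: float,
    shape1: InclusionShape,
    shape2: InclusionShape,
    om1: float,
    om2: float,
    n: int = 1440,
) -> float:
    """Signed minimum edge-to-edge separation (negative when overlapping)."""
    s1 = shape1.with_orientation(om1)
    s2 = shape2.with_orientation(om2)
    b1 = s1.boundary_points(n)
    b2 = s2.boundary_points(n, center=(d, 0.0))
    # penetration test: boundary points of one curve inside the other
    depth = 0.0
    for pts, other, center in ((b2, s1, (0.0, 0.0)), (b1, s2, (d, 0.0))):
        dx = pts[:, 0] - center[0]
        dy = pts[:, 1] - center[1]
        rho = np.hypot(dx, dy)
        rb = other.boundary_radius(np.arctan2(dy, dx))
        depth = max(depth, float(np.max(rb - rho)))
    if depth > 0.0:
        return -depth
    return float(cdist(b1, b2).min())


def min_center_distance(
    shape1: InclusionShape,
    shape2: InclusionShape,
    orientations: tuple[float, float],
    clearance: float = 0.8,
    *,
    n_samples: int = 1440,
    xtol: float = 1e-9,
) -> float:
    """Smallest centre distance at which the boundary gap equals ``clearance``.

    The minimum edge-to-edge separation between the two boundary curves is
    evaluated by dense angular sampling and the centre distance solved by a
    bracketed root find.  The default clearance of 0.8 nm represents the
    finite size of trimers and lipids.
    """
    if clearance < 0:
        raise ValueError("clearance must be non-negative")
    om1, om2 = orientations
    lo = 1e-3
    hi = shape1.max_radius + shape2.max_radius + clearance + 2.0

    def f(d):
        return _boundary_gap(d, shape1, shape2, om1, om2, n_samples) - clearance

    f_hi = f(hi)
    if f_hi < 0:
        raise ValueError("bad bracketing: shapes overlap at the upper bracket")
    return float(brentq(f, lo, hi, xtol=xtol))


@dataclass(frozen=True)
class LatticeSpec:
    """One of the three trimer lattice architectures.

    ``symmetry`` is ``"hexagonal"`` (6-coordinated, uniform trimer
    orientation), ``"honeycomb_face_on"`` or ``"honeycomb_tip_on"``
    (3-coordinated, two-sublattice orientation rule such that every bond
    realises the named pair configuration).  ``nearest_neighbor_distance``
    is the bond length in nm.
    """

    symmetry: str
    nearest_neighbor_distance: float

    _SYMMETRIES = ("hexagonal", "honeycomb_face_on", "honeycomb_tip_on")

    def __post_init__(self) -> None:
        if self.symmetry not in self._SYMMETRIES:
            raise ValueError(
                f"unknown symmetry {self.symmetry!r}; expected one of {self._SYMMETRIES}"
            )
        if self.nearest_neighbor_distance <= 0:
            raise ValueError("nearest_neighbor_distance must be positive")

    @property
    def coordination(self) -> int:
        return 6 if self.symmetry == "hexagonal" else 3


@dataclass(frozen=True)
class LatticeSite:
    position: tuple[float, float]
    orientation: float
    shell: int


def _orientation_rule(symmetry: str, sublattice: int) -> float:
    if symmetry == "hexagonal":
        return HEXAGONAL_UNIFORM_ORIENTATION
    if symmetry == "honeycomb_face_on":
        # A-faces point along the three bond directions (0, 120, 240 deg)
        return math.pi / 3 if sublattice == 0 else 0.0
    # honeycomb_tip_on: A-tips point along the bond directions
    return 0.0 if sublattice == 0 else math.pi / 3


def lattice_sites(spec: LatticeSpec, shells: int) -> list[LatticeSite]:
    """Central site plus ``shells`` neighbour shells with orientations.

    Shells are ranked by distance from the central site; the central site
    has shell index 0.  Nearest-neighbour counts are 6 for the hexagonal
    and 3 for the honeycomb lattices.
    """
    if shells < 1:
        raise ValueError("shells must be >= 1")
    d = spec.nearest_neighbor_distance
    pts: list[tuple[float, float, int]] = []  # (x, y, sublattice)
    if spec.symmetry == "hexagonal":
        a1 = np.array([d, 0.0])
        a2 = np.array([d / 2.0, d * math.sqrt(3.0) / 2.0])
        rng = range(-(shells + 2), shells + 3)
        for i in rng:
            for j in rng:
                p = i * a1 + j * a2
                pts.append((p[0], p[1], 0))
    else:
        # honeycomb: triangular Bravais lattice with two-site basis;
        # lattice constant sqrt(3) d, B displaced by bond vector (d, 0)
        a1 = math.sqrt(3.0) * d * np.array([math.sqrt(3.0) / 2.0, 0.5])
        a2 = math.sqrt(3.0) * d * np.array([math.sqrt(3.0) / 2.0, -0.5])
        rng = range(-(shells + 3), shells + 4)
        for i in rng:
            for j in rng:
                p = i * a1 + j * a2
                pts.append((p[0], p[1], 0))
                pts.append((p[0] + d, p[1], 1))
    arr = np.array([(x, y) for x, y, _ in pts])
    dist = np.hypot(arr[:, 0], arr[:, 1])
    order = np.argsort(dist)
    # group by distance into shells
    sites: list[LatticeSite] = []
    shell_idx = -1
    last = -1.0
    for k in order:
        dk = dist[k]
        if dk > last + 1e-9 * max(d, 1.0):
            shell_idx += 1
            last = dk
        if shell_idx > shells:
            break
        x, y, sub = pts[k]
        sites.append(
            LatticeSite(
                position=(float(x), float(y)),
                orientation=_orientation_rule(spec.symmetry, sub),
                shell=shell_idx,
            )
        )
    return sites


def area_per_trimer(spec: LatticeSpec) -> float:
    """Exact unit-cell membrane area per lattice site in nm^2.

    At equal nearest-neighbour distance the honeycomb lattice devotes
    exactly 50% more membrane area to each trimer than the hexagonal
    lattice: sqrt(3)/2 d^2 (hexagonal) versus 3 sqrt(3)/4 d^2 (honeycomb).
    """
    d = spec.nearest_neighbor_distance
    if spec.symmetry == "hexagonal":
        return math.sqrt(3.0) / 2.0 * d * d
    return 3.0 * math.sqrt(3.0) / 4.0 * d * d
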