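"""Parametric geometry of tubulin dimer assemblies.

All assemblies are described as ordered lists of subunit *poses*: the
center-of-mass position of one alpha/beta-tubulin heterodimer (nm) plus its
orientation as Tait-Bryan angles (degrees, rotations about the fixed x, y
and z axes, composed A = A_x(alpha) A_y(beta) A_z(gamma)).

Supported geometries:

* **Inverted helical tubule** — a single left-handed helix of dimers whose
  lumen-facing surface points outward (the inverse of microtubule geometry).
* **Conical spiral tubule** — a conical helix whose radius shrinks from
  ``R_max`` to ``R_min`` over ``n`` turns, stacked every ``V_h`` along z.
  Dimers are placed at equal arc-length increments along the spiral, found
  by a bracketed binary search on the closed-form arc length.
* **Bundles** — 2-D lattices of tubules: hexagonal (gamma = 120 deg) for
  parallel tubules, oblique (gamma = 105 deg) for the mixed
  parallel/antiparallel packing of conical spiral tubules.
* **Microtubule** — N_p straight protofilaments on a cylinder; a reference
  geometry rather than a fitted model.

Units are nm and degrees at every public interface; the z axis is the
tubule axis; the coordinate frame is right-handed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "SubunitPose",
    "HelicalTubuleSpec",
    "HelixDerived",
    "ConicalSpiralSpec",
    "ConeDerived",
    "LatticeSpec",
    "MicrotubuleSpec",
    "Assembly",
    "GeometryError",
    "tait_bryan_matrix",
    "matrix_to_tait_bryan",
    "turn_length",
    "cone_angle",
    "lattice_distances",
    "conical_arc_length",
    "solve_dimer_angles",
    "build_inverted_helical_tubule",
    "build_conical_spiral_tubule",
    "build_bundle",
    "build_microtubule",
    "single_dimer_assembly",
]


class GeometryError(ValueError):
    """Raised when requested parameters describe an impossible geometry."""


# --------------------------------------------------------------------------
# rotations
# --------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(b: float) -> np.ndarray:
    c, s = math.cos(b), math.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(g: float) -> np.ndarray:
    c, s = math.cos(g), math.sin(g)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def tait_bryan_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix ``A = A_x(alpha) @ A_y(beta) @ A_z(gamma)``.

    Parameters are the Tait-Bryan angles in **degrees** about the x, y and z
    axes respectively.  The result is orthonormal with determinant +1.
    """
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite Tait-Bryan angle {name}={v!r}")
    a, b, g = (math.radians(v) for v in (alpha, beta, gamma))
    return _rot_x(a) @ _rot_y(b) @ _rot_z(g)


def matrix_to_tait_bryan(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`tait_bryan_matrix`; returns angles in degrees.

    At the gimbal singularity (|beta| = 90 deg) gamma is set to zero and the
    remaining freedom is absorbed into alpha.
    """
    m = np.asarray(matrix, dtype=float)
    sb = float(np.clip(m[0, 2], -1.0, 1.0))
    beta = math.asin(sb)
    if abs(sb) < 1.0 - 1e-12:
        alpha = math.atan2(-m[1, 2], m[2, 2])
        gamma = math.atan2(-m[0, 1], m[0, 0])
    else:  # cos(beta) = 0: only alpha -/+ gamma is determined
        alpha = math.atan2(m[2, 1], m[1, 1])
        gamma = 0.0
    return math.degrees(alpha), math.degrees(beta), math.degrees(gamma)


# --------------------------------------------------------------------------
# pose / assembly containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubunitPose:
    """Center-of-mass position (nm) and Tait-Bryan orientation (deg) of one dimer."""

    x: float
    y: float
    z: float
    alpha: float
    beta: float
    gamma: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def rotation(self) -> np.ndarray:
        return tait_bryan_matrix(self.alpha, self.beta, self.gamma)


AssemblyKind = Literal[
    "helical_tubule", "conical_spiral_tubule", "bundle", "microtubule", "single_dimer"
]


@dataclass
class Assembly:
    """An ordered set of subunit poses plus provenance.

    ``positions`` is an (N, 3) array in nm, ``angles`` an (N, 3) array of
    Tait-Bryan angles in degrees (columns alpha, beta, gamma).
    """

    positions: np.ndarray
    angles: np.ndarray
    kind: str
    spec: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.positions.shape != self.angles.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and angles must both be (N, 3)")
        if self.positions.shape[0] == 0:
            raise ValueError("an assembly must contain at least one pose")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def poses(self) -> Iterator[SubunitPose]:
        for p, a in zip(self.positions, self.angles):
            yield SubunitPose(*p, *a)

    def rotation_matrices(self) -> np.ndarray:
        """(N, 3, 3) stack of pose rotation matrices."""
        return np.stack([tait_bryan_matrix(*a) for a in self.angles])


def single_dimer_assembly() -> Assembly:
    """One dimer at the origin with the identity orientation."""
    return Assembly(np.zeros((1, 3)), np.zeros((1, 3)), kind="single_dimer")


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelicalTubuleSpec:
    """Inverted helical tubule parameters (nm).

    r       helix radius to the dimer centers
    p       vertical pitch (center-to-center distance of successive turns)
    h       total height of the tubule
    L_dim   dimer length measured along the helical line
    T_dim   dimer thickness (used for bundle non-penetration bounds)
    """

    r: float
    p: float
    h: float
    L_dim: float = 8.0
    T_dim: float = 5.0
    handedness: str = "left"

    def __post_init__(self) -> None:
        if self.r <= 0 or self.h <= 0 or self.L_dim <= 0 or self.T_dim <= 0:
            raise GeometryError("r, h, L_dim, T_dim must all be positive")
        if self.p < 0:
            raise GeometryError("pitch p must be non-negative")
        if self.handedness not in ("left", "right"):
            raise GeometryError("handedness must be 'left' or 'right'")


@dataclass(frozen=True)
class HelixDerived:
    """Quantities derived from a :class:`HelicalTubuleSpec`."""

    L_turn: float           # arc length of one helical turn, nm
    theta_dim: float        # azimuthal advance per dimer, rad
    i_max: int              # last dimer index (i runs 0..i_max)
    theta_i: np.ndarray     # per-dimer azimuth, rad, in [0, 2*pi)


@dataclass(frozen=True)
class ConicalSpiralSpec:
    """Conical spiral tubule parameters (nm).

    R_max, R_min  maximal/minimal radii to the dimer centers
    p             vertical pitch of one helical turn
    n             helical turns per conical spiral
    V_h           vertical distance between successive conical spirals
    N_spirals     conical repeats stacked per tubule
    """

    R_max: float
    R_min: float
    p: float
    n: float = 3.0
    V_h: float = 10.0
    N_spirals: int = 1
    L_dim: float = 8.0
    T_dim: float = 5.0

    def __post_init__(self) -> None:
        if not (self.R_max >= self.R_min > 0):
            raise GeometryError("require R_max >= R_min > 0")
        if self.n < 1:
            raise GeometryError("at least one helical turn per conical spiral")
        if self.V_h <= 0:
            raise GeometryError("V_h must be positive")
        if self.N_spirals < 1:
            raise GeometryError("N_spirals must be >= 1")
        if self.p < 0 or self.L_dim <= 0 or self.T_dim <= 0:
            raise GeometryError("p must be >= 0; L_dim, T_dim positive")


@dataclass(frozen=True)
class ConeDerived:
    """Quantities derived from a :class:`ConicalSpiralSpec`."""

    C: float                # radius decrease per radian, nm/rad
    A: float                # vertical rise per radian, nm/rad
    theta_cone: float       # opening half-angle of the conical envelope, deg
    t_i: np.ndarray         # azimuthal parameter at each dimer center, rad
    dt_i: np.ndarray        # azimuthal increment spanned by each dimer, rad


@dataclass(frozen=True)
class LatticeSpec:
    """2-D bundle lattice.

    a              center-to-center distance of neighboring tubules, nm
    gamma_lattice  angle between the lattice vectors, degrees
    n1_range, n2_range  inclusive integer index bounds (lo, hi)
    disc_cutoff    hexagonal mode keeps copies with |R_n| <= disc_cutoff
                   (defaults to a * max index magnitude)
    sublattice_j   which law-of-cosines distance (b_1 or b_2) spaces the
                   parallel sublattices in oblique antiparallel mode
    """

    a: float
    gamma_lattice: float = 120.0
    n1_range: tuple[int, int] = (-1, 1)
    n2_range: tuple[int, int] = (-1, 1)
    disc_cutoff: float | None = None
    sublattice_j: int = 1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise GeometryError("lattice constant a must be positive")
        if not (0.0 < self.gamma_lattice < 180.0):
            raise GeometryError("gamma_lattice must lie in (0, 180) degrees")
        if self.sublattice_j not in (1, 2):
            raise GeometryError("sublattice_j must be 1 or 2")


@dataclass(frozen=True)
class MicrotubuleSpec:
    """Simple microtubule: N_p straight protofilaments on a cylinder."""

    N_p: int = 13
    r: float = 11.2
    h: float = 50.0
    axial_rise: float = 8.0

    def __post_init__(self) -> None:
        if self.N_p < 2:
            raise GeometryError("a microtubule needs at least 2 protofilaments")
        if self.r <= 0 or self.h < 0 or self.axial_rise <= 0:
            raise GeometryError("r and axial_rise must be positive, h >= 0")


# --------------------------------------------------------------------------
# scalar helpers
# --------------------------------------------------------------------------

def turn_length(r: float, p: float) -> float:
    """Arc length of one helical turn, ``sqrt(4 pi^2 r^2 + p^2)`` (nm)."""
    if r < 0 or p < 0:
        raise GeometryError("r and p must be non-negative")
    if r == 0 and p == 0:
        raise GeometryError("degenerate helix: r = p = 0")
    return math.hypot(2.0 * math.pi * r, p)


def cone_angle(R_max: float, R_min: float, V_h: float) -> float:
    """Opening half-angle of the conical envelope, degrees.

    ``theta = arctan((R_max - R_min) / V_h)`` — the angle the spiral's
    envelope makes with the tubule axis.
    """
    if V_h <= 0:
        raise GeometryError("V_h must be positive")
    if R_max < R_min:
        raise GeometryError("require R_max >= R_min")
    return math.degrees(math.atan((R_max - R_min) / V_h))


def lattice_distances(a: float, gamma_obl: float) -> tuple[float, float]:
    """Law-of-cosines center distances across an oblique lattice cell.

    Returns ``(b1, b2)`` with ``b1 = sqrt(2 a^2 (1 - cos gamma))`` and
    ``b2 = sqrt(2 a^2 (1 - cos(180 deg - gamma)))``.  For the oblique
    tubulin bundle (gamma = 105 deg) these are 1.59 a and 1.22 a.
    """
    if a <= 0:
        raise GeometryError("a must be positive")
    if not (0.0 < gamma_obl < 180.0):
        raise GeometryError("gamma must lie in (0, 180) degrees")
    g = math.radians(gamma_obl)
    b1 = math.sqrt(2.0 * a * a * (1.0 - math.cos(g)))
    b2 = math.sqrt(2.0 * a * a * (1.0 - math.cos(math.pi - g)))
    return b1, b2


# --------------------------------------------------------------------------
# inverted helical tubule
# --------------------------------------------------------------------------

# float-tie guard for count expressions that are exact integers in exact
# arithmetic (e.g. L_turn/L_dim = 10): keeps floor() from losing one subunit
# to the last bit of rounding.
_COUNT_EPS = 1e-9


def build_inverted_helical_tubule(
    spec: HelicalTubuleSpec,
    spacing: Literal["azimuthal", "arc"] = "azimuthal",
) -> tuple[Assembly, HelixDerived]:
    """Place dimers on a single helix of radius ``r`` and pitch ``p``.

    Successive dimers advance by a fixed azimuth ``theta_dim`` and rise by
    ``p * L_dim / L_turn`` so that one full turn climbs exactly one pitch.
    Orientations tilt each dimer along the local helix tangent
    (``alpha = 90 deg - asin(p / L_turn)``) and swing it around the axis
    (``beta = theta_i``).

    ``spacing`` selects the azimuthal step: ``"azimuthal"`` uses
    ``theta_dim = L_dim / r`` (the dimer length laid along the equatorial
    circle); ``"arc"`` uses ``theta_dim = 2 pi L_dim / L_turn`` so that the
    step measured along the 3-D helical line is exactly ``L_dim``, which is
    the zero-cone-angle limit of the conical spiral construction.  The two
    coincide when p = 0 and differ by O((p / L_turn)^2) otherwise.
    """
    r, p, h, L_dim = spec.r, spec.p, spec.h, spec.L_dim
    if L_dim > 2.0 * math.pi * r:
        raise GeometryError(
            f"dimer length L_dim={L_dim} exceeds the tubule circumference "
            f"2*pi*r={2 * math.pi * r:.6g}"
        )
    L_turn = turn_length(r, p)
    if spacing == "azimuthal":
        theta_dim = L_dim / r
    elif spacing == "arc":
        theta_dim = 2.0 * math.pi * L_dim / L_turn
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    if p == 0.0:
        # Flat ring: the height budget is meaningless; fill one full circle.
        i_max = int(math.floor(2.0 * math.pi / theta_dim + _COUNT_EPS)) - 1
        if i_max < 0:
            raise GeometryError("dimer does not fit on the ring")
    else:
        i_max = int(math.floor((h / p) * (L_turn / L_dim) + 1.0 + _COUNT_EPS))

    i = np.arange(i_max + 1)
    theta_i = np.mod(i * theta_dim, 2.0 * math.pi)
    x = r * np.cos(theta_i)
    y = r * np.sin(theta_i)
    z = i * p * L_dim / L_turn

    alpha = 90.0 - math.degrees(math.asin(p / L_turn))
    angles = np.column_stack(
        [np.full(i.size, alpha), np.degrees(theta_i), np.zeros(i.size)]
    )
    positions = np.column_stack([x, y, z])
    if spec.handedness == "right":
        positions[:, 1] *= -1.0
        angles[:, 1] *= -1.0

    asm = Assembly(positions, angles, kind="helical_tubule", spec=spec,
                   meta={"spacing": spacing})
    derived = HelixDerived(L_turn=L_turn, theta_dim=theta_dim, i_max=i_max,
                           theta_i=theta_i)
    return asm, derived


# --------------------------------------------------------------------------
# conical spiral tubule
# --------------------------------------------------------------------------

def conical_arc_length(
    t: float | np.ndarray, R_max: float, C: float, A: float
) -> float | np.ndarray:
    """Arc length of the conical spiral from parameter 0 to ``t`` (nm).

    The spiral is ``((R_max - C t) cos t, (R_max - C t) sin t, A t)``; its
    speed is ``sqrt((C t - R_max)^2 + C^2 + A^2)``, and for C > 0 the
    integral has the closed form

        S(t) = 1/(2C) [ u sqrt(u^2 + k^2) + k^2 asinh(u / k) ]  | u=-R_max .. Ct-R_max

    with ``k^2 = C^2 + A^2``.  C = 0 is the circular-helix limit
    ``t sqrt(R_max^2 + A^2)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("arc-length parameter t must be non-negative")
    if C < 0:
        raise ValueError("C must be non-negative")
    if C == 0.0:
        out = t_arr * math.hypot(R_max, A)
        return float(out) if np.isscalar(t) else out

    k = math.hypot(C, A)
    u0 = -R_max
    u1 = C * t_arr - R_max
    f0 = math.hypot(u0, k)
    f1 = np.hypot(u1, k)

    if np.all(u1 < 0.0):
        # cancellation-free rearrangement (u0, u1 both negative): the naive
        # antiderivative difference loses ~R^2/C of precision as C -> 0
        ssum = u1 + u0
        den1 = u1 * f1 + u0 * f0
        term1 = 0.5 * t_arr * ssum * (u1 * u1 + u0 * u0 + k * k) / den1
        den2 = u1 * f0 + u0 * f1
        arg = C * t_arr * ssum / den2
        small = np.abs(arg) < 1e-6
        ratio = np.where(small, 1.0 - arg * arg / 6.0,
                         np.arcsinh(np.where(small, 1.0, arg)) /
                         np.where(small, 1.0, arg))
        term2 = 0.5 * k * k * (t_arr * ssum / den2) * ratio
        out = term1 + term2
    else:
        def antideriv(u):
            return 0.5 * (u * np.sqrt(u * u + k * k) + k * k * np.arcsinh(u / k))

        out = (antideriv(u1) - antideriv(u0)) / C
    return float(out) if np.isscalar(t) else out


def _solve_next_t(
    t_prev: float,
    target_s: float,
    spec_like: tuple[float, float, float],
    tol: float,
    max_iter: int = 400,
) -> float:
    """Bisection for t with S(t) = target_s, bracketing above t_prev."""
    R_max, C, A = spec_like
    r_local = max(R_max - C * t_prev, 1e-6)
    step = 2.0 * (target_s - conical_arc_length(t_prev, R_max, C, A)) / math.hypot(
        r_local, A
    )
    lo, hi = t_prev, t_prev + max(step, 1e-9)
    for _ in range(200):  # expand until the target is bracketed
        if conical_arc_length(hi, R_max, C, A) >= target_s:
            break
        lo, hi = hi, hi + 2.0 * (hi - lo)
    else:
        raise GeometryError("failed to bracket the next dimer position")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s_mid = conical_arc_length(mid, R_max, C, A)
        if abs(s_mid - target_s) <= tol or (hi - lo) <= 4.0 * np.finfo(float).eps * max(
            1.0, mid
        ):
            return mid
        if s_mid < target_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_dimer_angles(
    spec: ConicalSpiralSpec, tol: float = 1e-14, max_iter: int = 400
) -> ConeDerived:
    """Azimuthal parameters ``t_i`` placing dimers at equal arc increments.

    ``t_0 = 0``; each subsequent ``t_i`` satisfies
    ``S(t_i) - S(t_{i-1}) = L_dim`` to within ``tol`` (nm), found by a
    bracketed binary search; the sequence stops at ``2 pi n``.  The number of
    dimers placed is ``floor(S(2 pi n) / L_dim) + 1``.

    ``tol`` is an absolute arc-length tolerance; values at or below
    ~1e-14 nm are limited by double-precision evaluation of S itself (the
    search then terminates at machine resolution in t).
    """
    C = (spec.R_max - spec.R_min) / (2.0 * math.pi * spec.n)
    A = spec.p / (2.0 * math.pi)
    t_end = 2.0 * math.pi * spec.n
    s_total = conical_arc_length(t_end, spec.R_max, C, A)
    if spec.L_dim > s_total:
        raise GeometryError("dimer longer than the whole conical spiral")
    n_dimers = int(math.floor(s_total / spec.L_dim + _COUNT_EPS)) + 1

    params = (spec.R_max, C, A)
    t = np.empty(n_dimers)
    t[0] = 0.0
    s_prev = 0.0
    for i in range(1, n_dimers):
        target = s_prev + spec.L_dim
        try:
            t[i] = _solve_next_t(t[i - 1], target, params, tol, max_iter)
        except GeometryError as exc:
            raise GeometryError(f"arc-length solve failed at dimer {i}: {exc}") from exc
        s_prev = conical_arc_length(t[i], spec.R_max, C, A)

    if n_dimers > 1:
        dt = np.diff(t)
        dt = np.append(dt, dt[-1])  # last dimer reuses the previous increment
    else:
        dt = np.array([spec.L_dim / math.hypot(spec.R_max, A)])

    theta = cone_angle(spec.R_max, spec.R_min, spec.V_h)
    return ConeDerived(C=C, A=A, theta_cone=theta, t_i=t, dt_i=dt)


def build_conical_spiral_tubule(
    spec: ConicalSpiralSpec, tol: float = 1e-14
) -> tuple[Assembly, ConeDerived]:
    """Build a conical spiral tubule: ``N_spirals`` stacked conical spirals.

    Each spiral follows ``((R_max - C t_i) cos t_i, (R_max - C t_i) sin t_i,
    A t_i)`` with the arc-length-equalized ``t_i`` from
    :func:`solve_dimer_angles`.  Dimer tilt uses the per-dimer rise:
    ``alpha_i = 90 deg - asin(A dt_i / L_dim)``, ``beta_i = t_i`` and
    ``gamma_i = 0``.  Copies are offset by ``V_h`` along z and the whole
    tubule is shifted by ``-z_max / 2`` so it is centered on the origin.
    """
    derived = solve_dimer_angles(spec, tol=tol)
    t, dt = derived.t_i, derived.dt_i
    radius = spec.R_max - derived.C * t
    x = radius * np.cos(t)
    y = radius * np.sin(t)
    z = derived.A * t

    sin_arg = np.clip(derived.A * dt / spec.L_dim, -1.0, 1.0)
    alpha = 90.0 - np.degrees(np.arcsin(sin_arg))
    beta = np.degrees(t)
    gamma = np.zeros_like(t)

    pos_one = np.column_stack([x, y, z])
    ang_one = np.column_stack([alpha, beta, gamma])

    offsets = np.arange(spec.N_spirals) * spec.V_h
    positions = np.vstack([pos_one + [0.0, 0.0, dz] for dz in offsets])
    angles = np.vstack([ang_one] * spec.N_spirals)

    positions[:, 2] -= positions[:, 2].max() / 2.0

    asm = Assembly(positions, angles, kind="conical_spiral_tubule", spec=spec)
    return asm, derived


# --------------------------------------------------------------------------
# bundles
# --------------------------------------------------------------------------

def _unit_radial_extent(unit: Assembly) -> float | None:
    """Non-penetration bound (minimum allowed lattice constant) for a unit."""
    s = unit.spec
    if isinstance(s, HelicalTubuleSpec):
        return 2.0 * s.r + s.T_dim
    if isinstance(s, ConicalSpiralSpec):
        return s.R_max + s.R_min + s.T_dim
    return None


def _replicate(
    unit: Assembly, shift: np.ndarray, flip: bool, gamma_corr: float
) -> tuple[np.ndarray, np.ndarray]:
    """One lattice copy: optional antiparallel flip + z alignment + translation."""
    if flip or gamma_corr != 0.0:
        R_copy = tait_bryan_matrix(180.0 if flip else 0.0, 0.0, gamma_corr)
        pos = unit.positions @ R_copy.T + shift
        ang = np.array(
            [matrix_to_tait_bryan(R_copy @ tait_bryan_matrix(*a)) for a in unit.angles]
        )
    else:
        pos = unit.positions + shift
        ang = unit.angles.copy()
    return pos, ang


def build_bundle(
    lattice: LatticeSpec,
    unit: Assembly,
    mode: Literal["hexagonal", "oblique_antiparallel"] = "hexagonal",
    check_penetration: bool = True,
) -> Assembly:
    """Replicate a tubule on a 2-D bundle lattice.

    ``hexagonal`` mode places parallel copies at ``n1 a1 + n2 a2``
    (``gamma_lattice`` defaults to 120 deg) and keeps those inside the disc
    ``|R_n| <= disc_cutoff``.

    ``oblique_antiparallel`` mode builds two interleaved sublattices of
    parallel tubules with primitive vectors ``2a (1, 0)`` and
    ``b_j (cos(90 + gamma/2), sin(90 + gamma/2))``, shifts the second by
    ``(a, 0)`` and flips it antiparallel (alpha = 180 deg); every copy also
    receives the in-plane alignment rotation
    ``gamma = atan2(R_n . y, R_n . x)`` so the units face the bundle center
    consistently.
    """
    a = lattice.a
    if check_penetration:
        bound = _unit_radial_extent(unit)
        if bound is not None and a < bound - 1e-9:
            raise GeometryError(
                f"lattice constant a={a} violates the non-penetration bound "
                f"a >= {bound:.6g} for this unit"
            )

    n1_lo, n1_hi = lattice.n1_range
    n2_lo, n2_hi = lattice.n2_range
    copies: list[tuple[np.ndarray, bool]] = []  # (2-D lattice vector, flipped?)

    if mode == "hexagonal":
        g = math.radians(lattice.gamma_lattice)
        a1 = a * np.array([1.0, 0.0])
        a2 = a * np.array([math.cos(g), math.sin(g)])
        n_max = max(abs(n1_lo), abs(n1_hi), abs(n2_lo), abs(n2_hi))
        cutoff = lattice.disc_cutoff if lattice.disc_cutoff is not None else a * max(
            n_max, 1
        )
        for n1 in range(n1_lo, n1_hi + 1):
            for n2 in range(n2_lo, n2_hi + 1):
                R_n = n1 * a1 + n2 * a2
                if np.linalg.norm(R_n) <= cutoff + 1e-9:
                    copies.append((R_n, False))
    elif mode == "oblique_antiparallel":
        b1, b2 = lattice_distances(a, lattice.gamma_lattice)
        b_j = b1 if lattice.sublattice_j == 1 else b2
        phi = math.radians(90.0 + lattice.gamma_lattice / 2.0)
        A1 = 2.0 * a * np.array([1.0, 0.0])
        A2 = b_j * np.array([math.cos(phi), math.sin(phi)])
        shift = np.array([a, 0.0])
        for n1 in range(n1_lo, n1_hi + 1):
            for n2 in range(n2_lo, n2_hi + 1):
                base = n1 * A1 + n2 * A2
                copies.append((base, False))
                copies.append((base + shift, True))
    else:
        raise ValueError(f"unknown bundle mode {mode!r}")

    if not copies:
        raise GeometryError("empty bundle: no lattice sites selected")

    all_pos, all_ang = [], []
    for R_n, flip in copies:
        if mode == "oblique_antiparallel":
            gamma_corr = (
                math.degrees(math.atan2(R_n[1], R_n[0]))
                if np.linalg.norm(R_n) > 1e-12
                else 0.0
            )
        else:
            gamma_corr = 0.0
        pos, ang = _replicate(unit, np.array([R_n[0], R_n[1], 0.0]), flip, gamma_corr)
        all_pos.append(pos)
        all_ang.append(ang)

    meta = {"mode": mode, "n_tubules": len(copies),
            "tubule_centers": np.array([c for c, _ in copies]),
            "tubule_flipped": np.array([f for _, f in copies])}
    return Assembly(
        np.vstack(all_pos), np.vstack(all_ang), kind="bundle",
        spec=(lattice, unit.spec), meta=meta,
    )


# --------------------------------------------------------------------------
# microtubule
# --------------------------------------------------------------------------

def build_microtubule(spec: MicrotubuleSpec) -> Assembly:
    """N_p straight protofilaments equally spaced on a cylinder.

    Each protofilament is a vertical stack of dimers with the given axial
    rise; dimer orientation carries the protofilament azimuth in beta.
    The stack is centered on z = 0.
    """
    n_layers = int(math.floor(spec.h / spec.axial_rise + _COUNT_EPS)) + 1
    phi = 2.0 * math.pi * np.arange(spec.N_p) / spec.N_p
    zs = np.arange(n_layers) * spec.axial_rise
    zs = zs - zs.mean()

    pos, ang = [], []
    for z in zs:
        for ph in phi:
            pos.append([spec.r * math.cos(ph), spec.r * math.sin(ph), z])
            ang.append([0.0, math.degrees(ph), 0.0])
    return Assembly(np.array(pos), np.array(ang), kind="microtubule", spec=spec)
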