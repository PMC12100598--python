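"""Geometry builders against analytic and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import tubulaxs.geometry as geo

# ---------------------------------------------------------------- rotations


def _elementary_product(alpha, beta, gamma):
    """Independent composition oracle: explicit A_x * A_y * A_z."""
    a, b, g = np.radians([alpha, beta, gamma])
    ax = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    ay = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    az = np.array([[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]])
    return ax @ ay @ az


def test_tait_bryan_identity_and_half_turn():
    assert np.allclose(geo.tait_bryan_matrix(0, 0, 0), np.eye(3))
    assert np.allclose(geo.tait_bryan_matrix(180, 0, 0), np.diag([1.0, -1.0, -1.0]))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.floats(-360, 360), st.floats(-360, 360), st.floats(-360, 360)
)
def test_tait_bryan_matches_elementary_composition(alpha, beta, gamma):
    m = geo.tait_bryan_matrix(alpha, beta, gamma)
    assert np.allclose(m, _elementary_product(alpha, beta, gamma), atol=1e-12)
    assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)


def test_tait_bryan_rejects_non_finite():
    with pytest.raises(ValueError, match="non-finite"):
        geo.tait_bryan_matrix(float("nan"), 0, 0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(-179, 179), st.floats(-89, 89), st.floats(-179, 179))
def test_matrix_angle_round_trip(alpha, beta, gamma):
    m = geo.tait_bryan_matrix(alpha, beta, gamma)
    back = geo.tait_bryan_matrix(*geo.matrix_to_tait_bryan(m))
    assert np.allclose(m, back, atol=1e-9)


# ------------------------------------------------------------- turn length


@pytest.mark.parametrize(
    "r,p,expected",
    [
        (0.0, 5.0, 5.0),
        (3.0, 0.0, 6.0 * math.pi),
        (10.0, 5.0, math.sqrt(400.0 * math.pi**2 + 25.0)),
    ],
)
def test_turn_length_values(r, p, expected):
    assert geo.turn_length(r, p) == pytest.approx(expected, rel=1e-14)


def test_turn_length_degenerate():
    with pytest.raises(geo.GeometryError):
        geo.turn_length(0.0, 0.0)


# ------------------------------------------------------ helical tubule


def test_helix_first_pose_on_x_axis():
    spec = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=60.0, L_dim=8.0)
    asm, derived = geo.build_inverted_helical_tubule(spec)
    assert np.allclose(asm.positions[0], [11.0, 0.0, 0.0])
    assert derived.theta_i[0] == 0.0


def test_flat_ring_equally_spaced():
    # r chosen so exactly 12 dimers tile the circle; p = 0 makes alpha = 90
    n = 12
    L = 8.0
    spec = geo.HelicalTubuleSpec(r=L * n / (2 * math.pi), p=0.0, h=10.0, L_dim=L)
    asm, derived = geo.build_inverted_helical_tubule(spec)
    assert len(asm) == n
    assert np.allclose(asm.angles[:, 0], 90.0)
    assert np.allclose(asm.positions[:, 2], 0.0)
    gaps = np.diff(np.sort(derived.theta_i))
    assert np.allclose(gaps, 2 * math.pi / n, atol=1e-9)


def test_helix_dimer_count_floor():
    # choose r, p so L_turn / L_dim = 10 exactly and h = p:
    # i_max = floor(1 * 10 + 1) = 11
    L = 8.0
    p = 12.0
    r = math.sqrt((10 * L) ** 2 - p**2) / (2 * math.pi)
    spec = geo.HelicalTubuleSpec(r=r, p=p, h=p, L_dim=L)
    asm, derived = geo.build_inverted_helical_tubule(spec)
    assert derived.L_turn / L == pytest.approx(10.0, rel=1e-12)
    assert derived.i_max == 11
    assert len(asm) == 12


def test_helix_rejects_oversized_dimer():
    with pytest.raises(geo.GeometryError, match="circumference"):
        geo.build_inverted_helical_tubule(
            geo.HelicalTubuleSpec(r=1.0, p=5.0, h=10.0, L_dim=8.0)
        )


def test_helix_pose_rotations_are_proper():
    spec = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=40.0)
    asm, _ = geo.build_inverted_helical_tubule(spec)
    for m in asm.rotation_matrices():
        assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)


def test_helix_chord_below_dimer_length_and_converges():
    # chord between successive centers is at most L_dim and approaches it
    # as the dimer becomes short against the tubule circumference
    for L, tol in [(8.0, 0.02), (0.5, 1e-4)]:
        spec = geo.HelicalTubuleSpec(r=20.0, p=6.0, h=12.0, L_dim=L)
        asm, _ = geo.build_inverted_helical_tubule(spec, spacing="arc")
        chords = np.linalg.norm(np.diff(asm.positions, axis=0), axis=1)
        assert np.all(chords <= L + 1e-12)
        assert chords.max() == pytest.approx(L, rel=tol)


def test_helix_handedness_flag_mirrors_y():
    spec_l = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=40.0)
    spec_r = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=40.0, handedness="right")
    left, _ = geo.build_inverted_helical_tubule(spec_l)
    right, _ = geo.build_inverted_helical_tubule(spec_r)
    assert np.allclose(right.positions * [1, -1, 1], left.positions)


def _torsion_sign(points):
    """Sign of the discrete torsion of a 3-D polyline (chirality indicator)."""
    d1 = np.diff(points, axis=0)
    signs = []
    for i in range(len(d1) - 2):
        signs.append(np.dot(np.cross(d1[i], d1[i + 1]), d1[i + 2]))
    return np.sign(np.median(signs))


def test_helix_handedness_flips_torsion_sign():
    base = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=60.0)
    mirrored = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=60.0, handedness="right")
    s_default = _torsion_sign(geo.build_inverted_helical_tubule(base)[0].positions)
    s_mirror = _torsion_sign(geo.build_inverted_helical_tubule(mirrored)[0].positions)
    assert s_default == -s_mirror != 0


# ------------------------------------------------------ conical arc length


def _quad_arc(t, R_max, C, A):
    f = lambda u: math.sqrt((C * u - R_max) ** 2 + C * C + A * A)
    val, _ = quad(f, 0.0, t, limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def test_arc_length_zero_and_circle_limits():
    assert geo.conical_arc_length(0.0, 10.0, 0.5, 0.3) == 0.0
    assert geo.conical_arc_length(2.0, 7.0, 0.0, 0.0) == pytest.approx(14.0)


def test_arc_length_matches_quadrature():
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(200):
        R = rng.uniform(5, 30)
        C = rng.uniform(0.01, 2.0)
        A = rng.uniform(0.0, 3.0)
        t = rng.uniform(0.0, 6 * math.pi)
        closed = geo.conical_arc_length(t, R, C, A)
        worst = max(worst, abs(closed - _quad_arc(t, R, C, A)))
    assert worst < 1e-9


def test_arc_length_rejects_negative_t():
    with pytest.raises(ValueError):
        geo.conical_arc_length(-0.1, 10.0, 0.5, 0.3)


# ------------------------------------------------------ dimer placement


def test_circle_placement_is_uniform():
    # C = 0, A = 0: t_i = i * L_dim / R exactly
    spec = geo.ConicalSpiralSpec(R_max=10.0, R_min=10.0, p=0.0, n=1, V_h=5.0,
                                 L_dim=2.0)
    d = geo.solve_dimer_angles(spec)
    expect = np.arange(d.t_i.size) * 2.0 / 10.0
    assert np.allclose(d.t_i, expect, atol=1e-12)


def test_placement_increments_match_arc_oracle():
    spec = geo.ConicalSpiralSpec(R_max=22.0, R_min=14.0, p=12.0, n=3, V_h=10.0,
                                 L_dim=8.0)
    d = geo.solve_dimer_angles(spec, tol=1e-13)
    s = geo.conical_arc_length(d.t_i, spec.R_max, d.C, d.A)
    incs = np.diff(s)
    s_total = geo.conical_arc_length(2 * math.pi * spec.n, spec.R_max, d.C, d.A)
    # absolute floor: S is evaluated in double precision at magnitude s_total
    tol = max(1e-13, 8 * np.finfo(float).eps * s_total)
    assert np.abs(incs - spec.L_dim).max() <= tol
    # dimer count equals the arc-length budget
    assert d.t_i.size == int(s_total // spec.L_dim) + 1


def test_first_dimer_matches_independent_bisection():
    from scipy.optimize import brentq

    spec = geo.ConicalSpiralSpec(R_max=22.0, R_min=14.0, p=12.0, n=3, V_h=10.0,
                                 L_dim=8.0)
    d = geo.solve_dimer_angles(spec)
    t1 = brentq(lambda t: _quad_arc(t, spec.R_max, d.C, d.A) - spec.L_dim,
                1e-6, 2.0, xtol=1e-13)
    assert d.t_i[1] == pytest.approx(t1, abs=1e-9)


# ------------------------------------------------------ conical tubule


def test_degenerate_cone_equals_arc_spaced_helix():
    rng = np.random.default_rng(11)
    for _ in range(20):
        R = rng.uniform(8, 20)
        p = rng.uniform(0.5, 15.0)
        L = rng.uniform(3.0, 8.0)
        n = int(rng.integers(1, 4))
        cs = geo.ConicalSpiralSpec(R_max=R, R_min=R, p=p, n=n, V_h=5.0, L_dim=L)
        casm, _ = geo.build_conical_spiral_tubule(cs)
        hs = geo.HelicalTubuleSpec(r=R, p=p, h=2.0 * p * n, L_dim=L)
        hasm, _ = geo.build_inverted_helical_tubule(hs, spacing="arc")
        m = min(len(casm), len(hasm))
        cz = casm.positions[:m] - casm.positions[0]
        hz = hasm.positions[:m] - hasm.positions[0]
        assert np.abs(cz - hz).max() < 1e-9


def test_conical_tubule_z_centering():
    spec = geo.ConicalSpiralSpec(R_max=22.0, R_min=14.0, p=12.0, n=3, V_h=11.0,
                                 N_spirals=3, L_dim=8.0)
    asm, _ = geo.build_conical_spiral_tubule(spec)
    z = asm.positions[:, 2]
    assert abs(z.max() + z.min()) <= spec.V_h  # symmetric within one V_h quantum
    assert z.max() == pytest.approx(-z.min() + (z.max() + z.min()), abs=1e-9)


def test_conical_tubule_stacking_offsets():
    spec = geo.ConicalSpiralSpec(R_max=20.0, R_min=15.0, p=10.0, n=2, V_h=9.0,
                                 N_spirals=2, L_dim=8.0)
    asm, d = geo.build_conical_spiral_tubule(spec)
    n1 = d.t_i.size
    assert len(asm) == 2 * n1
    dz = asm.positions[n1:, 2] - asm.positions[:n1, 2]
    assert np.allclose(dz, spec.V_h)
    assert np.allclose(asm.positions[n1:, :2], asm.positions[:n1, :2])


# ------------------------------------------------------ cone angle


@pytest.mark.parametrize("Rmax,Rmin,Vh,expected", [
    (15.0, 15.0, 10.0, 0.0),
    (18.0, 10.0, 8.0, 45.0),
])
def test_cone_angle_analytic_cases(Rmax, Rmin, Vh, expected):
    assert geo.cone_angle(Rmax, Rmin, Vh) == pytest.approx(expected, abs=1e-12)


def test_cone_angle_monotone_in_radius_gap():
    vals = [geo.cone_angle(10.0 + d, 10.0, 7.5) for d in np.linspace(0, 8, 15)]
    assert np.all(np.diff(vals) > 0)


def test_cone_angle_rejects_bad_vh():
    with pytest.raises(geo.GeometryError):
        geo.cone_angle(10.0, 8.0, 0.0)


# ------------------------------------------------------ lattices


def test_lattice_distances_oblique_printed_values():
    b1, b2 = geo.lattice_distances(1.0, 105.0)
    assert round(b1, 2) == 1.59
    assert round(b2, 2) == 1.22


def test_lattice_distances_symmetry_cases():
    b1, b2 = geo.lattice_distances(2.0, 90.0)
    assert b1 == pytest.approx(b2) == pytest.approx(2.0 * math.sqrt(2.0))
    b1, b2 = geo.lattice_distances(3.0, 120.0)
    assert b1 == pytest.approx(3.0 * math.sqrt(3.0))
    assert b2 == pytest.approx(3.0)


def _brute_force_hex_count(a, n_max, cutoff):
    g = math.radians(120.0)
    a1 = np.array([a, 0.0])
    a2 = a * np.array([math.cos(g), math.sin(g)])
    count = 0
    for n1 in range(-n_max, n_max + 1):
        for n2 in range(-n_max, n_max + 1):
            if np.linalg.norm(n1 * a1 + n2 * a2) <= cutoff + 1e-9:
                count += 1
    return count


def test_hexagonal_bundle_seven_tubules():
    unit = geo.single_dimer_assembly()
    lat = geo.LatticeSpec(a=30.0, n1_range=(-1, 1), n2_range=(-1, 1),
                          disc_cutoff=30.0)
    asm = geo.build_bundle(lat, unit, mode="hexagonal", check_penetration=False)
    assert asm.meta["n_tubules"] == 7 == _brute_force_hex_count(30.0, 1, 30.0)


@pytest.mark.parametrize("n_max", [1, 2, 3])
def test_hexagonal_bundle_count_matches_enumeration(n_max):
    unit = geo.single_dimer_assembly()
    lat = geo.LatticeSpec(a=30.0, n1_range=(-n_max, n_max),
                          n2_range=(-n_max, n_max), disc_cutoff=30.0 * n_max)
    asm = geo.build_bundle(lat, unit, mode="hexagonal", check_penetration=False)
    assert asm.meta["n_tubules"] == _brute_force_hex_count(30.0, n_max, 30.0 * n_max)


def test_single_copy_bundle_is_identity():
    spec = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=30.0)
    unit, _ = geo.build_inverted_helical_tubule(spec)
    lat = geo.LatticeSpec(a=2 * 11.0 + 5.0, n1_range=(0, 0), n2_range=(0, 0))
    asm = geo.build_bundle(lat, unit, mode="hexagonal")
    assert np.allclose(asm.positions, unit.positions)
    assert np.allclose(asm.angles, unit.angles)


def test_bundle_non_penetration_guard():
    spec = geo.HelicalTubuleSpec(r=11.0, p=12.0, h=30.0)
    unit, _ = geo.build_inverted_helical_tubule(spec)
    with pytest.raises(geo.GeometryError, match="non-penetration"):
        geo.build_bundle(geo.LatticeSpec(a=10.0), unit, mode="hexagonal")


def test_oblique_bundle_neighbor_classes():
    """Central tubule has 4 nearest antiparallel and 2 nearest parallel tubules."""
    unit = geo.single_dimer_assembly()
    a = 40.0
    lat = geo.LatticeSpec(a=a, gamma_lattice=105.0, n1_range=(-1, 1),
                          n2_range=(-1, 1))
    asm = geo.build_bundle(lat, unit, mode="oblique_antiparallel",
                           check_penetration=False)
    centers = asm.meta["tubule_centers"]
    flipped = asm.meta["tubule_flipped"]
    # distances from the central (unflipped, at origin) tubule
    d = np.linalg.norm(centers, axis=1)
    order = np.argsort(d)
    assert d[order[0]] == pytest.approx(0.0)
    nearest4 = order[1:5]
    assert np.allclose(d[nearest4], a, rtol=1e-6)      # at the lattice constant
    assert flipped[nearest4].all()                      # all antiparallel
    # the next shell: two parallel tubules at |A1 + A2| of the sublattice
    b1, _ = geo.lattice_distances(a, 105.0)
    phi = math.radians(90.0 + 105.0 / 2.0)
    expected = np.linalg.norm(2 * a * np.array([1.0, 0.0]) +
                              b1 * np.array([math.cos(phi), math.sin(phi)]))
    next2 = order[5:7]
    assert np.allclose(d[next2], expected, rtol=1e-6)
    assert not flipped[next2].any()                     # parallel


def test_oblique_antiparallel_orientation_flip():
    unit = geo.single_dimer_assembly()
    lat = geo.LatticeSpec(a=40.0, gamma_lattice=105.0, n1_range=(0, 0),
                          n2_range=(0, 0))
    asm = geo.build_bundle(lat, unit, mode="oblique_antiparallel",
                           check_penetration=False)
    flipped_idx = np.nonzero(asm.meta["tubule_flipped"])[0]
    rot = asm.rotation_matrices()[flipped_idx[0]]
    # an antiparallel copy points its z axis down
    assert rot[2, 2] == pytest.approx(-1.0, abs=1e-9)


# ------------------------------------------------------ microtubule


def test_microtubule_equal_azimuths():
    asm = geo.build_microtubule(geo.MicrotubuleSpec(N_p=13, r=11.2, h=0.0))
    assert len(asm) == 13
    az = np.degrees(np.arctan2(asm.positions[:, 1], asm.positions[:, 0]))
    gaps = np.diff(np.sort(np.mod(az, 360.0)))
    assert np.allclose(gaps, 360.0 / 13, atol=1e-9)


def test_microtubule_neighbor_chord():
    spec = geo.MicrotubuleSpec(N_p=11, r=10.0, h=0.0)
    asm = geo.build_microtubule(spec)
    d = np.linalg.norm(asm.positions[1] - asm.positions[0])
    assert d == pytest.approx(2 * 10.0 * math.sin(math.pi / 11), rel=1e-12)


def test_microtubule_minimal_and_invalid():
    asm = geo.build_microtubule(geo.MicrotubuleSpec(N_p=2, r=5.0, h=0.0))
    assert np.allclose(asm.positions[0], -asm.positions[1])
    with pytest.raises(geo.GeometryError):
        geo.MicrotubuleSpec(N_p=1)
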