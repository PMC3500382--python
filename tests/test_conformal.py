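"""Exterior Schwarz-Christoffel map: parameter problem, forward/inverse."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma

from huddlesim import conformal as cf
from huddlesim.lattice import boundary_traversal, generate_initial_huddle

TWO_PI = 2 * np.pi


def make_poly(vertices):
    v = np.asarray(vertices, dtype=complex)
    return cf.ScaledPolygon(v, np.arange(len(v)), 1.0)


@pytest.fixture(scope="module")
def square_map():
    sq = np.array([1 + 1j, -1 + 1j, -1 - 1j, 1 - 1j])
    return cf.solve_parameter_problem(make_poly(sq))


@pytest.fixture(scope="module")
def quad_map():
    """Irregular quadrilateral."""
    q = np.array([1.3 + 0.2j, -0.1 + 1.1j, -1.2 - 0.3j, 0.4 - 1.0j])
    return cf.solve_parameter_problem(make_poly(q))


# -- scaling -----------------------------------------------------------------

def test_length_scale_closed_form():
    # L = sqrt(N * (sqrt(3)/2) / pi)
    assert cf.huddle_length_scale(100) == pytest.approx(
        np.sqrt(100 * np.sqrt(3) / 2 / np.pi))
    assert cf.huddle_length_scale(100) == pytest.approx(5.25, abs=0.01)


def test_scaled_polygon_is_centred_and_order_one(hex19):
    trav = boundary_traversal(hex19)
    poly = cf.scale_polygon(trav, hex19.N)
    # shoelace centroid at the origin
    v, w = poly.vertices, np.roll(poly.vertices, -1)
    cross = v.real * w.imag - w.real * v.imag
    cx = np.sum((v.real + w.real) * cross) / (3 * np.sum(cross))
    assert abs(cx) < 1e-12
    assert 0.3 * np.pi < poly.area() < 1.05 * np.pi


def test_disk_huddle_scales_to_unit_radius():
    from huddlesim.thermal import disk_huddle
    h = disk_huddle(200)
    poly = cf.scale_polygon(boundary_traversal(h), 200)
    radii = np.abs(poly.corners)
    assert radii.mean() == pytest.approx(1.0, rel=0.06)


# -- parameter problem -------------------------------------------------------

def test_square_prevertices_equally_spaced(square_map):
    gaps = np.diff(np.append(square_map.theta,
                             square_map.theta[0] + TWO_PI))
    assert np.allclose(gaps, np.pi / 2, atol=1e-8)
    assert square_map.residual < cf.TOL_MAP


def test_square_capacity_closed_form(square_map):
    # logarithmic capacity of a square of side s: s * Gamma(1/4)^2 / (4 pi^{3/2})
    side = 2.0
    expected = side * gamma(0.25) ** 2 / (4 * np.pi ** 1.5)
    assert square_map.capacity == pytest.approx(expected, rel=1e-10)


def test_regular_hexagon_prevertices_equally_spaced(hex7):
    trav = boundary_traversal(hex7)
    poly = cf.scale_polygon(trav, hex7.N)
    m = cf.solve_parameter_problem(poly)
    gaps = np.diff(np.append(m.theta, m.theta[0] + TWO_PI))
    assert np.allclose(gaps, TWO_PI / 6, atol=1e-8)


def test_quadrilateral_vertices_match_refined_quadrature(quad_map):
    """Independent oracle: evaluate the side integrals of f' with scipy's
    adaptive quadrature (which handles the integrable endpoint
    singularities) and rebuild the vertex images."""
    m = quad_map
    th_ext = np.append(m.theta, m.theta[0] + TWO_PI)
    beta = m.beta

    def integrand(t, part):
        val = np.exp(np.sum(beta * np.log(1 - np.exp(1j * (m.theta - t))))
                     ) * 1j * np.exp(1j * t)
        return val.real if part == 0 else val.imag

    J = []
    for k in range(m.n):
        re = quad(integrand, th_ext[k], th_ext[k + 1], args=(0,),
                  limit=200)[0]
        im = quad(integrand, th_ext[k], th_ext[k + 1], args=(1,),
                  limit=200)[0]
        J.append(re + 1j * im)
    J = np.array(J)
    C_oracle = (m.corners[1] - m.corners[0]) / J[0]
    assert abs(C_oracle - m.C) < 1e-7
    images = m.corners[0] + C_oracle * np.concatenate(
        [[0], np.cumsum(J[:-1])])
    assert np.max(np.abs(images - m.corners)) < cf.TOL_MAP


def test_sum_of_turning_parameters_is_two(quad_map, square_map):
    for m in (quad_map, square_map):
        assert m.beta.sum() == pytest.approx(2.0, abs=1e-12)
        # closure: sum beta_k z_k = 0
        assert abs(np.sum(m.beta * m.prevertex_points)) < 1e-8


# -- forward map -------------------------------------------------------------

def test_prevertices_map_to_corners(quad_map):
    for k in range(quad_map.n):
        z = np.exp(1j * quad_map.theta[k])
        assert abs(quad_map.forward(z) - quad_map.corners[k]) < cf.TOL_MAP


def test_far_field_expansion(quad_map):
    """f(zeta) ~ C zeta + c0 + c1/zeta, with c0, c1 fitted far away."""
    m = quad_map
    zfar = 50 * np.exp(1j * np.linspace(0.1, TWO_PI, 8, endpoint=False))
    resid = m.forward(zfar) - m.C * zfar
    c0 = np.mean(resid)
    c1 = np.mean((resid - c0) * zfar)
    z10 = 10 * np.exp(1j * 2.0)
    # truncating after c0 leaves an O(|c1|/rho) error; including c1 an
    # O(1/rho^2) one
    assert abs(m.forward(z10) - (m.C * z10 + c0)) < 2 * abs(c1) / 10
    assert abs(m.forward(z10) - (m.C * z10 + c0 + c1 / z10)) < 1e-3


def test_arc_midpoint_lands_on_polygon_side(square_map):
    m = square_map
    for k in range(4):
        th_mid = 0.5 * (m.theta[k] + m.theta[(k + 1) % 4]
                        + (TWO_PI if k == 3 else 0))
        z = m.forward(np.exp(1j * th_mid))
        a, b = m.corners[k], m.corners[(k + 1) % 4]
        # point-to-segment distance
        t = np.clip(((z - a) / (b - a)).real, 0, 1)
        assert abs(z - (a + t * (b - a))) < cf.TOL_MAP


def test_conformality_at_random_exterior_points(quad_map, rng):
    """Images of two tiny orthogonal steps stay orthogonal."""
    m = quad_map
    h = 1e-5
    for _ in range(10):
        z = (rng.uniform(1.5, 4) * np.exp(1j * rng.uniform(0, TWO_PI)))
        f0 = m.forward(z)
        dx = m.forward(z + h) - f0
        dy = m.forward(z + 1j * h) - f0
        ang = np.angle(dy / dx)
        assert abs(ang - np.pi / 2) < 1e-3


# -- inverse map -------------------------------------------------------------

def test_inverse_round_trip(quad_map, rng):
    m = quad_map
    pts = []
    while len(pts) < 200:
        z = rng.uniform(-5, 5) + 1j * rng.uniform(-5, 5)
        if abs(z) > 2.0:
            pts.append(z)
    pts = np.array(pts)
    zeta = m.inverse(pts)
    assert np.all(np.abs(zeta) >= 1 - 1e-12)
    assert np.max(np.abs(m.forward(zeta) - pts)) < 10 * cf.TOL_INV


def test_inverse_of_vertex_is_prevertex(quad_map):
    m = quad_map
    z = m.corners[2] * (1 + 1e-9)  # nudge outward off the corner
    zeta = m.inverse(z)
    assert abs(np.angle(zeta) % TWO_PI - m.theta[2] % TWO_PI) < 1e-3


def test_boundary_preimage_is_monotone_on_square_side(square_map):
    m = square_map
    s_targets = np.array([0.3, 0.9, 1.5])  # side length is 2
    sq = m.side_quad(0)
    th = sq.invert(s_targets)
    assert np.all(np.diff(th) > 0)
    assert np.all((th > m.theta[0]) & (th < m.theta[1]))
    # forward maps back onto the expected boundary points
    a, b = m.corners[0], m.corners[1]
    expect = a + s_targets / 2.0 * (b - a)
    got = m.forward(np.exp(1j * th))
    assert np.max(np.abs(got - expect)) < 1e-6


# -- invariance properties ---------------------------------------------------

@pytest.mark.parametrize("rot", [0.3, 1.7])
@pytest.mark.parametrize("scale", [0.5, 2.0])
def test_capacity_rotates_invariantly_and_scales_linearly(rot, scale):
    q = np.array([1.3 + 0.2j, -0.1 + 1.1j, -1.2 - 0.3j, 0.4 - 1.0j])
    base = cf.solve_parameter_problem(make_poly(q)).capacity
    rotated = cf.solve_parameter_problem(
        make_poly(q * np.exp(1j * rot))).capacity
    scaled = cf.solve_parameter_problem(make_poly(q * scale)).capacity
    assert rotated == pytest.approx(base, rel=1e-8)
    assert scaled == pytest.approx(scale * base, rel=1e-8)


def test_huddle_boundary_is_a_streamline():
    """The streamfunction Im F(S^-1(z)) is constant (zero) along the huddle
    polygon: sampled boundary points pull back to the unit circle."""
    h = generate_initial_huddle(40, 2)
    trav = boundary_traversal(h)
    poly = cf.scale_polygon(trav, 40)
    m = cf.solve_parameter_problem(poly)
    v = poly.vertices
    psi = []
    for k in range(len(v)):
        edge = (np.roll(v, -1) - v)[k]
        n_out = -1j * edge / abs(edge)  # outward normal of a CCW edge
        for t in (0.15, 0.4, 0.6, 0.85):
            z = v[k] + t * edge + 1e-7 * n_out
            zeta = m.inverse(z)
            psi.append((zeta + 1 / zeta).imag)
    psi = np.array(psi)
    assert len(psi) >= 100
    assert np.max(np.abs(psi)) < 1e-5


# -- canonical flow ----------------------------------------------------------

def test_canonical_velocity_special_points():
    u_r, u_t = cf.canonical_velocity(np.array([1.0 + 0j, -1.0 + 0j]))
    assert np.allclose(u_r, 0, atol=1e-14)
    assert np.allclose(u_t, 0, atol=1e-14)
    # top of the cylinder: purely tangential, speed 2
    u_r, u_t = cf.canonical_velocity(np.exp(1j * np.pi / 2))
    assert u_r == pytest.approx(0, abs=1e-14)
    assert abs(u_t) == pytest.approx(2.0)
    # far field: uniform (1, 0)
    u_r, u_t = cf.canonical_velocity(1e6 + 0j)
    assert u_r == pytest.approx(1.0, abs=1e-9)


def test_forward_rejects_interior_points(square_map):
    with pytest.raises(ValueError):
        square_map.forward(0.5 + 0j)
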