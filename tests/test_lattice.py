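"""Hex-lattice geometry, huddle invariants, boundary extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from huddlesim import lattice
from huddlesim.lattice import (
    DegenerateShapeError,
    Huddle,
    InvalidHuddleError,
    boundary_traversal,
    cartesian,
    eligible_sites,
    generate_initial_huddle,
    neighbors,
    validate_removal,
)

SQRT3 = np.sqrt(3.0)


# -- independent oracles -----------------------------------------------------

def bfs_connected(sites):
    """Flood-fill connectivity oracle, independent of scipy."""
    sites = set(sites)
    seen = {next(iter(sites))}
    stack = list(seen)
    while stack:
        s = stack.pop()
        for nb in neighbors(s):
            if nb in sites and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == sites


def bfs_has_hole(sites):
    """Flood-fill hole oracle: complement cells unreachable from a frame."""
    sites = set(sites)
    aa = [a for a, _ in sites]
    bb = [b for _, b in sites]
    lo_a, hi_a = min(aa) - 1, max(aa) + 1
    lo_b, hi_b = min(bb) - 1, max(bb) + 1
    empty = {(a, b) for a in range(lo_a, hi_a + 1)
             for b in range(lo_b, hi_b + 1)} - sites
    start = (lo_a, lo_b)
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for nb in neighbors(s):
            if nb in empty and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen != empty


# -- neighbours --------------------------------------------------------------

def test_neighbors_are_unit_distance_and_ccw():
    nbs = neighbors((0, 0))
    assert len(nbs) == 6
    xy = np.array([cartesian(s) for s in nbs])
    assert np.allclose(np.hypot(xy[:, 0], xy[:, 1]), 1.0)
    angles = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
    assert np.allclose(np.diff(angles), np.pi / 3)  # CCW, starting at +x
    assert nbs[0] == (1, 0)


@given(a=st.integers(-50, 50), b=st.integers(-50, 50),
       k=st.integers(0, 5))
@settings(max_examples=50, derandomize=True)
def test_neighbor_symmetry_and_translation(a, b, k):
    s = (a, b)
    nb = neighbors(s)[k]
    assert s in neighbors(nb)
    base = neighbors((0, 0))
    assert neighbors(s) == [(p + a, q + b) for p, q in base]


# -- huddle generation -------------------------------------------------------

def test_generate_minimal_huddle_every_penguin_has_two_neighbors():
    h = generate_initial_huddle(5, seed=0)
    assert h.N == 5
    assert all(h.neighbor_count(s) >= 2 for s in h.sites)


def test_generation_is_deterministic_under_fixed_seed():
    assert generate_initial_huddle(7, 99) == generate_initial_huddle(7, 99)
    assert generate_initial_huddle(40, 3) == generate_initial_huddle(40, 3)


@pytest.mark.parametrize("seed", [0, 1, 17])
def test_generated_huddles_are_connected_and_hole_free(seed):
    h = generate_initial_huddle(50, seed)
    assert h.N == 50
    assert bfs_connected(h.sites)
    assert not bfs_has_hole(h.sites)
    h.validate()


def test_generation_rejects_tiny_n():
    with pytest.raises(ValueError):
        generate_initial_huddle(4, 0)


# -- eligibility -------------------------------------------------------------

def test_eligible_sites_of_filled_hexagon_touch_two_ring_penguins(hex7):
    for site in eligible_sites(hex7):
        assert hex7.neighbor_count(site) >= 2


def test_eligible_sites_strip_matches_exhaustive_check(strip2x10):
    """Every unoccupied neighbour of the strip, checked against the three
    growth conditions by brute force."""
    candidates = {nb for s in strip2x10.sites for nb in neighbors(s)
                  if nb not in strip2x10.sites}
    expected = set()
    for c in candidates:
        if strip2x10.neighbor_count(c) < 2:
            continue
        grown = set(strip2x10.sites) | {c}
        if bfs_has_hole(grown):
            continue
        expected.add(c)
    assert eligible_sites(strip2x10) == expected
    # concave end-notch sites are in; single-contact sites are out
    assert all(strip2x10.neighbor_count(c) >= 2 for c in expected)


@pytest.mark.parametrize("n,seed", [(12, 0), (30, 5)])
def test_occupying_any_eligible_site_revalidates(n, seed):
    h = generate_initial_huddle(n, seed)
    for site in eligible_sites(h):
        h.with_site(site).validate()


# -- boundary traversal ------------------------------------------------------

def test_hex7_boundary_is_regular_hexagon(hex7):
    trav = boundary_traversal(hex7)
    assert trav.n == 6
    assert len(hex7.interior_sites()) == 1
    sides = np.linalg.norm(
        np.roll(trav.polygon, -1, axis=0) - trav.polygon, axis=1)
    assert np.allclose(sides, 1.0)
    assert not trav.collinear.any()


def test_five_penguin_huddle_is_all_boundary():
    h = Huddle(lattice.SEED_SITES)
    trav = boundary_traversal(h)
    assert trav.n == 5
    assert set(trav.order) == h.sites


@pytest.mark.parametrize("seed", [0, 2, 9])
def test_polygon_area_matches_picks_theorem(seed):
    """Pick's theorem on the triangular lattice: the polygon through the
    boundary penguin centres encloses area
    (sqrt(3)/2) * (interior + boundary/2 - 1)."""
    h = generate_initial_huddle(50, seed)
    trav = boundary_traversal(h)
    poly = trav.polygon
    area = 0.5 * abs(np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                            - np.roll(poly[:, 0], -1) * poly[:, 1]))
    n_int = len(h.interior_sites())
    n_bnd = trav.n
    expected = (SQRT3 / 2) * (n_int + n_bnd / 2 - 1)
    assert area == pytest.approx(expected, rel=1e-12)
    assert n_int + n_bnd == h.N


def test_pinched_huddle_raises_degenerate_shape():
    # two triangles joined at a single cut vertex (bowtie)
    left = [(-1, 0), (-2, 1), (-1, 1), (-2, 0)]
    right = [(1, 0), (2, 0), (1, 1), (2, -1), (1, -1)]
    pinch = Huddle(left + right + [(0, 0)])
    with pytest.raises(DegenerateShapeError):
        boundary_traversal(pinch)


# -- removal -----------------------------------------------------------------

def test_removal_of_two_neighbor_tip_is_valid(hex19):
    # grow a 2-wide bump; its outermost penguins have exactly two contacts
    h = hex19.with_site((3, -1)).with_site((3, 0))
    h.validate()
    assert h.neighbor_count((3, 0)) == 2
    assert validate_removal(h, (3, 0))


def test_removal_that_strands_a_neighbor_is_invalid(hex19):
    h = hex19.with_site((3, -1)).with_site((3, 0))
    # removing (3,-1) would leave (3,0) with a single contact
    assert not validate_removal(h, (3, -1))


def test_removal_that_would_pinch_or_disconnect_is_invalid():
    # Dumbbell: two rhombi joined through a 2-penguin bridge.  Removing
    # either bridge penguin leaves the huddle hanging together through a
    # single cut penguin -- the polygon pinches, the state is rejected.
    blob1 = [(0, 0), (1, 0), (0, 1), (1, -1)]
    bridge = [(2, 0), (2, -1)]
    blob2 = [(3, 0), (4, 0), (3, -1), (4, -1)]
    h = Huddle(blob1 + bridge + blob2)
    for s in bridge:
        rest = set(h.sites) - {s}
        assert bfs_connected(rest)  # still connected, but only just...
        assert not validate_removal(h, s)  # ...so the removal is refused

    # a raw one-penguin bridge: removing it genuinely disconnects
    h2 = Huddle(blob1 + [(2, -1)] + blob2)
    assert not bfs_connected(set(h2.sites) - {(2, -1)})
    assert not validate_removal(h2, (2, -1))


def test_removal_requires_occupied_site(hex7):
    with pytest.raises(InvalidHuddleError):
        validate_removal(hex7, (5, 5))


# -- serialization -----------------------------------------------------------

def test_csv_round_trip(tmp_path):
    h = generate_initial_huddle(23, 4)
    p = tmp_path / "huddle.csv"
    h.to_csv(p)
    assert Huddle.from_csv(p) == h


def test_csv_loader_revalidates(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("a,b\n0,0\n5,5\n6,5\n7,5\n8,5\n")  # disconnected
    with pytest.raises(InvalidHuddleError):
        Huddle.from_csv(p)
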