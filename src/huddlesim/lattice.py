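"""Hexagonal-lattice geometry of a penguin huddle.

Penguins stand on the sites of a hexagonal (triangular) lattice with unit
spacing equal to one penguin diameter.  Sites are addressed by integer axial
coordinates ``(a, b)`` with the Cartesian embedding

    x = a + b / 2,        y = b * sqrt(3) / 2,

so the six lattice neighbours of a site are all at Cartesian distance 1 and
the wind blows along +x.

A *huddle* is a finite set of occupied sites that is

* connected under the 6-neighbour relation,
* free of enclosed empty sites (hole-free),
* such that every penguin has at least two occupied neighbours, and
* such that the closed polygon obtained by connecting the boundary penguins
  (those with fewer than six occupied neighbours) in counterclockwise order
  is simple.

These conditions guarantee that the huddle boundary is a simple polygon whose
vertices are penguin centres, which is what the flow solver downstream needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

SQRT3 = 1.7320508075688772

Site = tuple[int, int]

#: The six axial neighbour offsets in counterclockwise order, starting at +x.
AXIAL_DIRECTIONS: tuple[Site, ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
)

#: 6-connectivity structuring element for the axial grid (scipy.ndimage).
HEX_STRUCTURE = np.array([[0, 1, 1],
                          [1, 1, 1],
                          [1, 1, 0]], dtype=bool)

#: Fixed compact five-penguin seed used to start huddle growth.
SEED_SITES: frozenset[Site] = frozenset(
    {(0, 0), (1, 0), (0, 1), (-1, 1), (1, -1)}
)


class LatticeError(Exception):
    """Base class for lattice-level failures."""


class InvalidHuddleError(LatticeError):
    """A huddle violates a structural invariant."""


class DegenerateShapeError(LatticeError):
    """The boundary polygon is not simple (pinched huddle)."""


def neighbors(site: Site) -> list[Site]:
    """Return the six lattice neighbours of *site*, CCW starting from +x."""
    a, b = site
    return [(a + da, b + db) for da, db in AXIAL_DIRECTIONS]


def cartesian(site: Site) -> tuple[float, float]:
    """Cartesian position of a site (unit lattice spacing)."""
    a, b = site
    return (a + 0.5 * b, 0.5 * SQRT3 * b)


def cartesian_xy(sites: Iterable[Site]) -> np.ndarray:
    """Cartesian positions of many sites as an ``(n, 2)`` array."""
    arr = np.asarray(list(sites), dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    out = np.empty_like(arr)
    out[:, 0] = arr[:, 0] + 0.5 * arr[:, 1]
    out[:, 1] = 0.5 * SQRT3 * arr[:, 1]
    return out


def _occupancy_grid(sites: frozenset[Site], pad: int = 1):
    """Boolean occupancy array plus the axial origin of its [0,0] cell."""
    aa = [s[0] for s in sites]
    bb = [s[1] for s in sites]
    a0, b0 = min(aa) - pad, min(bb) - pad
    grid = np.zeros((max(aa) - a0 + 1 + pad, max(bb) - b0 + 1 + pad), bool)
    for a, b in sites:
        grid[a - a0, b - b0] = True
    return grid, (a0, b0)


def is_connected(sites: frozenset[Site]) -> bool:
    """True iff the occupied set is 6-connected."""
    if len(sites) <= 1:
        return True
    grid, _ = _occupancy_grid(sites, pad=0)
    _, num = ndimage.label(grid, structure=HEX_STRUCTURE)
    return num == 1


def has_hole(sites: frozenset[Site]) -> bool:
    """True iff some unoccupied site is enclosed by the huddle.

    Flood fill of the complement from a one-cell frame around the bounding
    box: any unoccupied component that does not touch the frame is a hole.
    """
    grid, _ = _occupancy_grid(sites, pad=1)
    labels, num = ndimage.label(~grid, structure=HEX_STRUCTURE)
    if num <= 1:
        return False
    exterior = labels[0, 0]
    return bool(np.any(labels[(labels != 0) & (labels != exterior)]))


class Huddle:
    """An immutable set of occupied hex-lattice sites.

    Construction does not validate; call :meth:`validate` (or use
    :meth:`from_sites`) to enforce the huddle invariants.
    """

    __slots__ = ("sites",)

    def __init__(self, sites: Iterable[Site]):
        self.sites = frozenset((int(a), int(b)) for a, b in sites)

    # -- basic queries -----------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.sites)

    def __contains__(self, site: Site) -> bool:
        return tuple(site) in self.sites

    def __eq__(self, other) -> bool:
        return isinstance(other, Huddle) and self.sites == other.sites

    def __hash__(self) -> int:
        return hash(self.sites)

    def __repr__(self) -> str:
        return f"Huddle(N={self.N})"

    def neighbor_count(self, site: Site) -> int:
        return sum(nb in self.sites for nb in neighbors(site))

    def boundary_sites(self) -> set[Site]:
        """Occupied sites with fewer than six occupied neighbours."""
        return {s for s in self.sites if self.neighbor_count(s) < 6}

    def interior_sites(self) -> set[Site]:
        return {s for s in self.sites if self.neighbor_count(s) == 6}

    # -- derived huddles ---------------------------------------------------

    def with_site(self, site: Site) -> "Huddle":
        return Huddle(self.sites | {tuple(site)})

    def without_site(self, site: Site) -> "Huddle":
        return Huddle(self.sites - {tuple(site)})

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise if any huddle invariant is violated."""
        if self.N < 5:
            raise InvalidHuddleError(f"huddle has {self.N} < 5 penguins")
        for s in self.sites:
            if self.neighbor_count(s) < 2:
                raise InvalidHuddleError(
                    f"site {s} has {self.neighbor_count(s)} < 2 neighbours")
        if not is_connected(self.sites):
            raise InvalidHuddleError("huddle is disconnected")
        if has_hole(self.sites):
            raise InvalidHuddleError("huddle encloses empty sites")
        boundary_traversal(self)  # raises DegenerateShapeError if pinched

    @classmethod
    def from_sites(cls, sites: Iterable[Site]) -> "Huddle":
        h = cls(sites)
        h.validate()
        return h

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write one ``a,b`` row per occupied site (sorted, with header)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["a", "b"])
            for a, b in sorted(self.sites):
                w.writerow([a, b])

    @classmethod
    def from_csv(cls, path) -> "Huddle":
        """Load and re-validate a huddle written by :meth:`to_csv`."""
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or [c.strip() for c in rows[0]] != ["a", "b"]:
            raise InvalidHuddleError(f"{path}: expected header 'a,b'")
        sites = [(int(r[0]), int(r[1])) for r in rows[1:] if r]
        return cls.from_sites(sites)


@dataclass(frozen=True)
class BoundaryTraversal:
    """Counterclockwise-ordered boundary penguins and their polygon.

    ``order[i]`` is the i-th boundary penguin; ``polygon[i]`` its Cartesian
    position.  ``collinear[i]`` flags penguins that sit in the interior of a
    straight polygon side (zero turning); they remain part of the traversal
    for per-penguin heat accounting but are dropped as conformal-map
    vertices.
    """

    order: tuple[Site, ...]
    polygon: np.ndarray
    collinear: np.ndarray

    @property
    def n(self) -> int:
        return len(self.order)

    def index_of(self, site: Site) -> int:
        return self.order.index(tuple(site))


def boundary_traversal(huddle: Huddle) -> BoundaryTraversal:
    """Trace the huddle boundary counterclockwise.

    Contour following on the hex grid: start from the lowest (then leftmost)
    penguin and repeatedly take the first occupied neighbour scanning CCW
    from just past the backtrack direction.  Raises
    :class:`DegenerateShapeError` when the contour visits a site twice (a
    pinched huddle whose polygon would self-intersect) or fails to cover all
    boundary penguins.
    """
    sites = huddle.sites
    if len(sites) < 3:
        raise InvalidHuddleError("need at least 3 penguins for a boundary")
    boundary = huddle.boundary_sites()

    start = min(sites, key=lambda s: (s[1], s[0]))
    # Virtual arrival at `start` moving along direction 1 so that the scan
    # begins at direction 5; the cell below-left of `start` is empty.
    prev_move = 1
    current = start
    order: list[Site] = []
    first_move = None
    for _ in range(6 * len(sites) + 6):
        back = (prev_move + 3) % 6
        move = None
        for k in range(1, 7):
            d = (back + k) % 6
            da, db = AXIAL_DIRECTIONS[d]
            nb = (current[0] + da, current[1] + db)
            if nb in sites:
                move = d
                nxt = nb
                break
        if move is None:  # isolated site; cannot occur for valid huddles
            raise InvalidHuddleError(f"site {current} has no neighbours")
        if first_move is None:
            first_move = move
        elif current == start and move == first_move:
            break
        order.append(current)
        current, prev_move = nxt, move
    else:
        raise DegenerateShapeError("boundary trace failed to close")

    if len(set(order)) != len(order):
        raise DegenerateShapeError("boundary polygon touches itself")
    if set(order) != boundary:
        raise DegenerateShapeError(
            "boundary trace does not cover all boundary penguins")

    poly = cartesian_xy(order)
    nv = len(order)
    prev_edge = poly - np.roll(poly, 1, axis=0)
    next_edge = np.roll(poly, -1, axis=0) - poly
    cross = prev_edge[:, 0] * next_edge[:, 1] - prev_edge[:, 1] * next_edge[:, 0]
    collinear = np.abs(cross) < 1e-9

    # CCW check (shoelace)
    area2 = float(np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                         - np.roll(poly[:, 0], -1) * poly[:, 1]))
    if area2 <= 0:
        raise DegenerateShapeError("boundary polygon is not counterclockwise")
    if nv - int(collinear.sum()) < 3:
        raise DegenerateShapeError("fewer than 3 polygon corners")
    return BoundaryTraversal(tuple(order), poly, collinear)


def addition_valid(huddle: Huddle, site: Site) -> bool:
    """True iff occupying *site* preserves all huddle invariants."""
    site = tuple(site)
    if site in huddle.sites:
        return False
    if huddle.neighbor_count(site) < 2:
        return False
    grown = huddle.with_site(site)
    if has_hole(grown.sites):
        return False
    try:
        boundary_traversal(grown)
    except LatticeError:
        return False
    return True


def eligible_sites(huddle: Huddle) -> set[Site]:
    """Unoccupied sites whose occupation preserves all huddle invariants."""
    candidates = {nb for s in huddle.boundary_sites() for nb in neighbors(s)
                  if nb not in huddle.sites}
    return {c for c in candidates if addition_valid(huddle, c)}


def validate_removal(huddle: Huddle, site: Site) -> bool:
    """True iff removing *site* leaves a valid huddle.

    Removal of a boundary penguin cannot create a hole (its cell touches the
    exterior), so only the neighbour-count, connectivity and simple-polygon
    conditions need rechecking.
    """
    site = tuple(site)
    if site not in huddle.sites:
        raise InvalidHuddleError(f"site {site} is not occupied")
    if huddle.neighbor_count(site) == 6:
        return False  # interior penguins never move
    shrunk = huddle.without_site(site)
    if shrunk.N < 5:
        return False
    for nb in neighbors(site):
        if nb in shrunk.sites and shrunk.neighbor_count(nb) < 2:
            return False
    if not is_connected(shrunk.sites):
        return False
    try:
        boundary_traversal(shrunk)
    except LatticeError:
        return False
    return True


def generate_initial_huddle(N: int, seed) -> Huddle:
    """Grow a random huddle of *N* penguins from the fixed 5-penguin seed.

    Penguins are added one at a time, uniformly at random among the eligible
    sites (adjacent to the huddle, at least two occupied neighbours after
    placement, creating no enclosed empty space, keeping the boundary
    polygon simple).  *seed* may be an int or a ``numpy.random.Generator``;
    the stream is independent of the dynamics RNG so that initial conditions
    are reproducible across noise sweeps.
    """
    if N < 5:
        raise ValueError(f"N must be >= 5, got {N}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    huddle = Huddle(SEED_SITES)
    while huddle.N < N:
        # Uniform over the eligible set via rejection: draw from the cheap
        # superset (>= 2 occupied neighbours), discard draws that fail the
        # full check.  Discarded candidates are removed before redrawing, so
        # the accepted draw is uniform over the truly eligible sites.
        candidates = sorted({
            nb for s in huddle.boundary_sites() for nb in neighbors(s)
            if nb not in huddle.sites and huddle.neighbor_count(nb) >= 2
        })
        placed = False
        while candidates:
            idx = int(rng.integers(len(candidates)))
            site = candidates.pop(idx)
            if addition_valid(huddle, site):
                huddle = huddle.with_site(site)
                placed = True
                break
        if not placed:  # cannot occur for valid growth states
            raise LatticeError(
                f"no eligible growth site at N={huddle.N}")
    return huddle
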