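"""Steady advection-diffusion temperature field and per-penguin heat loss.

In nondimensional variables (temperature scaled so the huddle edge is at
T = 1 and the far field at T = 0, lengths scaled by the huddle size L,
velocity by the far-field wind speed) the temperature satisfies

    Pe * (u . grad T) = laplacian T ,

with the Péclet number Pe = U L / kappa measuring wind strength against
(turbulent) thermal diffusion.  Because advection-diffusion with a
potential-flow velocity is invariant under conformal mapping, the equation
is solved once and for all in the canonical domain -- the annulus
1 <= r <= R outside the unit disk, with the Joukowsky flow past the disk --
and only the Schwarz-Christoffel boundary correspondence changes as the
huddle evolves.  Boundary conditions: T = 1 on r = 1 (penguin surface
temperature effectively constant), T = 0 on r = R (ambient), periodic in
the angle.

The discrete operator uses centred finite differences on a uniform polar
grid, exactly as one would write them down on regions of equal radius and
angle increments, assembled sparse and solved directly.  The outward heat
flux density at the huddle surface is the one-sided difference

    f(theta) = (T(1, theta) - T(1 + dr, theta)) / dr  >=  0,

and penguin i loses the integral of f over its preimage arc between the
preimages of the physical midpoints separating it from its boundary
neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .conformal import (
    ExteriorMap,
    ScaledPolygon,
    TWO_PI,
    canonical_velocity_polar_grid,
    scale_polygon,
    solve_parameter_problem,
)
from .lattice import Huddle, boundary_traversal

DEFAULT_R = 4.0
DEFAULT_NR = 60
DEFAULT_NTHETA = 180


class StabilityWarning(UserWarning):
    """Cell Péclet number exceeds the centred-difference comfort zone."""


@dataclass(frozen=True)
class AnnulusGrid:
    """Temperature on the canonical annulus 1 <= r <= R."""

    R: float
    Pe: float
    r: np.ndarray       # (n_r,) uniform, r[0] = 1, r[-1] = R
    theta: np.ndarray   # (n_theta,) uniform in [0, 2*pi)
    T: np.ndarray       # (n_r, n_theta)

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def dtheta(self) -> float:
        return float(self.theta[1] - self.theta[0])


@dataclass(frozen=True)
class HeatLossProfile:
    """Per-boundary-penguin heat loss, aligned with a boundary traversal.

    ``q[i]`` is the heat lost by boundary penguin i (traversal order);
    ``midpoint_angles[i]`` is the canonical preimage angle of the physical
    midpoint between boundary penguins i and i+1.  Interior penguins lose a
    negligible amount by convention (q = 0, not stored).  ``qbar`` is the
    disk-reference average loss used to scale random perturbations.
    """

    midpoint_angles: np.ndarray
    q: np.ndarray
    qbar: float | None = None

    @property
    def total(self) -> float:
        return float(self.q.sum())


# ---------------------------------------------------------------------------
# temperature solve (canonical domain; huddle-independent)
# ---------------------------------------------------------------------------

_temperature_cache: dict = {}
_MAX_CACHE = 8


def suggested_grid(Pe: float, R: float = DEFAULT_R) -> tuple[int, int]:
    """Grid sizes keeping the cell Péclet number at or below one.

    Radial: Pe * |u_r| * dr / 2 <= 1 with |u_r| <= 1;
    angular: Pe * |u_theta| * r * dtheta / 2 <= 1, where r * |u_theta|
    peaks at R + 1/R near the outer rim.
    """
    n_r = max(DEFAULT_NR, int(np.ceil((R - 1.0) * Pe / 2.0)) + 2)
    n_theta = max(DEFAULT_NTHETA,
                  int(np.ceil(np.pi * Pe * (R + 1.0 / R))))
    return n_r, n_theta


def solve_temperature(emap: ExteriorMap | None, Pe: float,
                      R: float = DEFAULT_R,
                      n_r: int = DEFAULT_NR, n_theta: int = DEFAULT_NTHETA,
                      capacity_correction: bool = False) -> AnnulusGrid:
    """Solve the canonical advection-diffusion problem on the annulus.

    The velocity is the Joukowsky flow past the unit disk, so the solution
    does not depend on the huddle shape; *emap* is only consulted when
    *capacity_correction* is on, in which case the effective Péclet number
    is multiplied by the map capacity (the physical far-field speed
    transforms by 1/|C|).  Results are cached per parameter set.
    """
    if Pe < 0:
        raise ValueError("Pe must be nonnegative")
    if R <= 1:
        raise ValueError("outer radius must exceed 1")
    if n_r < 3 or n_theta < 8:
        raise ValueError("grid too coarse (need n_r >= 3, n_theta >= 8)")
    pe_eff = float(Pe)
    if capacity_correction:
        if emap is None:
            raise ValueError("capacity correction requires a map")
        pe_eff *= emap.capacity

    key = (round(pe_eff, 12), float(R), int(n_r), int(n_theta))
    hit = _temperature_cache.get(key)
    if hit is not None:
        return hit

    r = np.linspace(1.0, R, n_r)
    theta = np.arange(n_theta) * (TWO_PI / n_theta)
    dr = r[1] - r[0]
    dth = theta[1] - theta[0]
    u_r, u_t = canonical_velocity_polar_grid(r, theta)

    cell_pe_r = pe_eff * np.abs(u_r).max() * dr / 2.0
    cell_pe_t = pe_eff * (np.abs(u_t) * r[:, None]).max() * dth / 2.0
    if max(cell_pe_r, cell_pe_t) > 1.0 + 1e-9:
        sr, st = suggested_grid(pe_eff, R)
        warnings.warn(
            f"cell Péclet {max(cell_pe_r, cell_pe_t):.2f} > 1 at "
            f"(n_r={n_r}, n_theta={n_theta}); centred differences may "
            f"oscillate -- consider n_r >= {sr}, n_theta >= {st}",
            StabilityWarning, stacklevel=2)

    idx = np.arange(n_r * n_theta).reshape(n_r, n_theta)
    rows, cols, data = [], [], []
    b = np.zeros(n_r * n_theta)

    # Dirichlet rows
    for i, val in ((0, 1.0), (n_r - 1, 0.0)):
        rows.extend(idx[i])
        cols.extend(idx[i])
        data.extend(np.ones(n_theta))
        b[idx[i]] = val

    ii = np.arange(1, n_r - 1)
    ri = r[ii][:, None]                       # (n_r-2, 1)
    uri = u_r[ii]                             # (n_r-2, n_theta)
    uti = u_t[ii]
    jj = np.arange(n_theta)[None, :]

    center = idx[ii]
    north = idx[ii + 1]
    south = idx[ii - 1]
    east = idx[ii][:, (jj[0] + 1) % n_theta]
    west = idx[ii][:, (jj[0] - 1) % n_theta]

    c_center = (-2.0 / dr ** 2 - 2.0 / (ri ** 2 * dth ** 2)) \
        * np.ones_like(uri)
    c_north = (1.0 / dr ** 2 + 1.0 / (2 * ri * dr)
               - pe_eff * uri / (2 * dr))
    c_south = (1.0 / dr ** 2 - 1.0 / (2 * ri * dr)
               + pe_eff * uri / (2 * dr))
    c_east = (1.0 / (ri ** 2 * dth ** 2)
              - pe_eff * uti / (2 * ri * dth))
    c_west = (1.0 / (ri ** 2 * dth ** 2)
              + pe_eff * uti / (2 * ri * dth))

    for nb, cf_ in ((center, c_center), (north, c_north), (south, c_south),
                    (east, c_east), (west, c_west)):
        rows.extend(center.ravel())
        cols.extend(nb.ravel())
        data.extend(cf_.ravel())

    A = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_r * n_theta, n_r * n_theta))
    T = spsolve(A.tocsc(), b).reshape(n_r, n_theta)
    T[0, :] = 1.0    # Dirichlet rows, exact by construction
    T[-1, :] = 0.0

    grid = AnnulusGrid(R=float(R), Pe=pe_eff, r=r, theta=theta, T=T)
    if len(_temperature_cache) >= _MAX_CACHE:
        _temperature_cache.pop(next(iter(_temperature_cache)))
    _temperature_cache[key] = grid
    return grid


def boundary_flux(grid: AnnulusGrid) -> np.ndarray:
    """Outward heat-flux density at the unit circle, per angular node.

    One-sided difference (T(1) - T(1+dr)) / dr as the discrete normal
    derivative; positive everywhere since heat is always lost.
    """
    return (grid.T[0] - grid.T[1]) / grid.dr


# ---------------------------------------------------------------------------
# heat loss per penguin
# ---------------------------------------------------------------------------

def midpoint_preimages(emap: ExteriorMap, poly: ScaledPolygon) -> np.ndarray:
    """Preimage angles of the midpoints between consecutive boundary
    penguins, in traversal order.

    Midpoint i lies halfway between boundary penguins i and i+1, on the
    polygon side that contains both; its canonical angle is found by
    inverting the image-arclength function of that side's prevertex arc.
    Returned angles increase cyclically around the circle (mod 2*pi).
    """
    v = poly.vertices
    nb = len(v)
    ci = poly.corner_idx
    ncor = len(ci)
    seg = np.abs(np.roll(v, -1) - v)          # spacing, == 1/L on the lattice
    cum = np.concatenate([[0.0], np.cumsum(seg)])   # cum[i]: arclength to v_i
    perim = cum[-1]
    corner_cum = cum[ci]

    # arclength of midpoint i (between v_i and v_{i+1}), measured from v_0
    mid_cum = cum[:nb] + 0.5 * seg

    # fold into the frame starting at the first corner
    u = (mid_cum - corner_cum[0]) % perim
    corner_u = np.concatenate([corner_cum - corner_cum[0], [perim]])
    side_of = np.searchsorted(corner_u, u, side="right") - 1
    side_of = np.clip(side_of, 0, ncor - 1)
    s_local = u - corner_u[side_of]

    angles = np.empty(nb)
    for k in np.unique(side_of):
        sel = side_of == k
        sq = emap.side_quad(int(k))
        angles[sel] = sq.invert(s_local[sel])
    return np.mod(angles, TWO_PI)


def _flux_cumulative(flux: np.ndarray, dtheta: float):
    """Exact cumulative integral of the periodic linear interpolant of the
    flux samples; returns (F(x) callable, total integral)."""
    f_ext = np.append(flux, flux[0])
    seg = 0.5 * (f_ext[:-1] + f_ext[1:]) * dtheta
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    n = len(flux)

    def F(x):
        x = np.mod(np.asarray(x, dtype=float), TWO_PI)
        j = np.minimum((x / dtheta).astype(int), n - 1)
        t = x - j * dtheta
        fj = f_ext[j]
        slope = (f_ext[j + 1] - f_ext[j]) / dtheta
        return cum[j] + fj * t + 0.5 * slope * t ** 2

    return F, total


def heat_loss_per_penguin(flux: np.ndarray, midpoint_angles: np.ndarray,
                          dtheta: float | None = None,
                          qbar: float | None = None) -> HeatLossProfile:
    """Integrate the boundary flux over each penguin's preimage arc.

    q_i = integral of f between the preimages of the midpoints flanking
    penguin i.  The trapezoid cumulative is evaluated exactly at the arc
    endpoints, so the q_i partition the full-circle flux integral to
    machine precision.
    """
    if dtheta is None:
        dtheta = TWO_PI / len(flux)
    F, total = _flux_cumulative(flux, dtheta)
    m = np.asarray(midpoint_angles, dtype=float)
    Fm = F(m)
    q = Fm - np.roll(Fm, 1)        # arc of penguin i: [m_{i-1}, m_i]
    q = np.where(q < 0, q + total, q)
    # exactly one wraparound: enforce the partition identity
    excess = q.sum() - total
    if abs(excess) > 1e-9 * max(total, 1.0):
        # should not happen for monotone midpoints
        raise ValueError("midpoint angles are not cyclically ordered")
    return HeatLossProfile(midpoint_angles=m, q=q, qbar=qbar)


# ---------------------------------------------------------------------------
# disk reference huddle and Qbar
# ---------------------------------------------------------------------------

def disk_huddle(N: int) -> Huddle:
    """Deterministic near-disk huddle: concentric rings filled in order.

    Ring k holds 6*k sites walked counterclockwise; a partially filled
    outermost ring is a contiguous arc started at a mid-edge site so every
    penguin keeps at least two neighbours.
    """
    if N < 5:
        raise ValueError("N must be >= 5")
    sites = [(0, 0)]
    k = 0
    while len(sites) < N:
        k += 1
        ring = []
        a, b = k, 0
        for da, db in [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]:
            for _ in range(k):
                ring.append((a, b))
                a, b = a + da, b + db
        shift = k // 2   # start at a mid-edge site
        ring = ring[shift:] + ring[:shift]
        take = min(N - len(sites), len(ring))
        sites.extend(ring[:take])
    return Huddle(sites)


_qbar_cache: dict = {}


def disk_reference_loss(N: int, Pe: float, R: float = DEFAULT_R,
                        n_r: int = DEFAULT_NR, n_theta: int = DEFAULT_NTHETA,
                        mode: str = "boundary") -> float:
    """Average heat loss of the equal-N disk-shaped huddle (Qbar).

    Runs the full flow + temperature pipeline once on the deterministic
    disk huddle and averages q over its boundary penguins (default), or
    over all N when ``mode='all'``.  The value is cached: it stays constant
    throughout an iterative simulation.
    """
    if mode not in ("boundary", "all"):
        raise ValueError("mode must be 'boundary' or 'all'")
    key = (N, round(float(Pe), 12), float(R), n_r, n_theta, mode)
    hit = _qbar_cache.get(key)
    if hit is not None:
        return hit
    huddle = disk_huddle(N)
    trav = boundary_traversal(huddle)
    poly = scale_polygon(trav, N)
    emap = solve_parameter_problem(poly)
    grid = solve_temperature(emap, Pe, R, n_r, n_theta)
    flux = boundary_flux(grid)
    m = midpoint_preimages(emap, poly)
    prof = heat_loss_per_penguin(flux, m, grid.dtheta)
    qbar = prof.total / (len(prof.q) if mode == "boundary" else N)
    _qbar_cache[key] = qbar
    return qbar
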