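"""Exterior Schwarz-Christoffel map and the potential-flow wind field.

The wind around the huddle is an inviscid, irrotational potential flow.  In
the *canonical domain* -- the exterior of the unit disk -- the complex
potential of uniform flow past the disk is the Joukowsky transform

    F(zeta) = zeta + 1/zeta        (far-field speed 1 along +x),

and the physical flow outside the polygonal huddle boundary is F composed
with the inverse of a conformal map f from the disk exterior to the polygon
exterior.  For a simple CCW polygon with corners ``w_k`` and turning angles
``pi*beta_k`` (sum beta_k = 2), the map has the derivative

    f'(zeta) = C * prod_k (1 - z_k / zeta)**beta_k ,      z_k = e^{i theta_k},

with prevertices ``theta_k`` on the unit circle and a constant ``C`` whose
modulus is the logarithmic capacity of the polygon exterior.  Requiring f to
be single valued imposes the closure condition ``sum_k beta_k z_k = 0``.

The *parameter problem* -- finding the prevertices -- is solved in log-gap
variables with one angle gauge-fixed, matching side-length ratios plus the
closure condition, and all arc integrals use compound Gauss-Jacobi
quadrature so that the integrable endpoint singularities are handled
exactly.  After solving, the canonical frame is rotated so that C is real
and positive: the canonical far-field flow direction then coincides with the
physical wind (+x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.special import roots_jacobi, roots_legendre

from .lattice import BoundaryTraversal

TWO_PI = 2.0 * np.pi

#: Hexagon cell area at unit lattice spacing (one penguin's share of ground).
CELL_AREA = np.sqrt(3.0) / 2.0

#: Default tolerances; far below the thermal grid discretisation error.
TOL_MAP = 1e-6
TOL_INV = 1e-8
GAP_MIN = 1e-6

#: Accept-with-warning threshold for the vertex-image residual: beyond this
#: the parameter solve is considered failed.
TOL_FAIL = 1e-3


class MapFailureError(Exception):
    """The SC parameter problem did not converge."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


class InverseFailureError(Exception):
    """Newton iteration for the inverse map did not converge."""


class CrowdingWarning(UserWarning):
    """Adjacent prevertices closer than ``GAP_MIN`` (elongated huddle)."""


# ---------------------------------------------------------------------------
# scaled polygon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledPolygon:
    """Huddle boundary in nondimensional units.

    Distances are divided by the huddle length scale ``L`` -- the radius of
    the disk that holds the same number of penguins at hexagonal packing,
    ``L = sqrt(N * A_cell / pi)`` with ``A_cell = sqrt(3)/2`` -- and the
    polygon centroid is moved to the origin.  ``vertices`` holds *every*
    boundary penguin (as complex numbers, CCW); ``corner_idx`` indexes the
    true corners (nonzero turning), which are the conformal-map vertices.
    """

    vertices: np.ndarray
    corner_idx: np.ndarray
    L: float

    @property
    def corners(self) -> np.ndarray:
        return self.vertices[self.corner_idx]

    @property
    def n_corners(self) -> int:
        return len(self.corner_idx)

    def area(self) -> float:
        v = self.vertices
        w = np.roll(v, -1)
        return 0.5 * float(np.sum(v.real * w.imag - w.real * v.imag))


def huddle_length_scale(N: int) -> float:
    """Radius of the equal-area disk huddle, in lattice units."""
    return float(np.sqrt(N * CELL_AREA / np.pi))


def scale_polygon(boundary: BoundaryTraversal, N: int) -> ScaledPolygon:
    """Nondimensionalise a boundary traversal (divide by L, centre)."""
    L = huddle_length_scale(N)
    pts = boundary.polygon[:, 0] + 1j * boundary.polygon[:, 1]
    nxt = np.roll(pts, -1)
    cross = pts.real * nxt.imag - nxt.real * pts.imag
    area = 0.5 * float(np.sum(cross))
    if area <= 0:
        raise ValueError("polygon must be CCW with positive area")
    cx = float(np.sum((pts.real + nxt.real) * cross)) / (6 * area)
    cy = float(np.sum((pts.imag + nxt.imag) * cross)) / (6 * area)
    v = (pts - (cx + 1j * cy)) / L
    corner_idx = np.flatnonzero(~boundary.collinear)
    return ScaledPolygon(v, corner_idx, L)


# ---------------------------------------------------------------------------
# quadrature primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _gj_rule(p: int, beta_key: int):
    """Gauss-Jacobi nodes/weights on [-1, 1] for weight (1+t)^beta."""
    beta = beta_key / 1e9
    return roots_jacobi(p, 0.0, beta)


@lru_cache(maxsize=32)
def _gl_rule(p: int):
    return roots_legendre(p)


def _bkey(beta: float) -> int:
    return int(round(beta * 1e9))


def _log_abs_prod(nodes: np.ndarray, theta: np.ndarray,
                  beta: np.ndarray) -> np.ndarray:
    """sum_j beta_j * ln|2 sin((nodes - theta_j)/2)| for each node."""
    d = nodes[:, None] - theta[None, :]
    return np.log(np.abs(2.0 * np.sin(0.5 * d))) @ beta


def _log_cplx_prod(nodes: np.ndarray, theta: np.ndarray,
                   beta: np.ndarray) -> np.ndarray:
    """sum_j beta_j * Log(1 - e^{i(theta_j - nodes)}) (principal logs).

    Each factor lies in the closed right half-plane, so the principal branch
    is continuous along prevertex arcs.
    """
    d = theta[None, :] - nodes[:, None]
    return np.log(1.0 - np.exp(1j * d)) @ beta.astype(complex)


def _integrand_abs(nodes, theta, beta, sing_idx=None, u=None):
    """|prod (1 - z_j/z)^{beta_j}| on the unit circle, with the singular
    factor |node - theta_sing|^beta divided out when *sing_idx* is given.

    *u* holds the analytic angular offsets of the nodes from the singular
    prevertex; using them (rather than rounded differences) keeps the
    evaluation finite arbitrarily close to the singularity.
    """
    d = nodes[:, None] - theta[None, :]
    logmat = np.log(np.maximum(np.abs(2.0 * np.sin(0.5 * d)), 1e-300))
    if sing_idx is not None:
        logmat[:, sing_idx] = np.log(2.0 * np.sin(0.5 * u))
    lg = logmat @ beta
    if sing_idx is not None:
        lg = lg - beta[sing_idx] * np.log(u)
    return np.exp(lg)


def _integrand_cplx(nodes, theta, beta, sing_idx=None, u=None,
                    sgn: float = -1.0):
    """prod (1 - z_j/z)^{beta_j} * i e^{i theta} on the unit circle (the
    integrand of f'/C in the angle variable), optionally desingularised.

    *sgn* is -1 when the nodes sit above the singular prevertex
    (node = origin + u) and +1 below it (node = origin - u).
    """
    d = theta[None, :] - nodes[:, None]
    fac = 1.0 - np.exp(1j * d)
    tiny = np.abs(fac) < 1e-300
    if np.any(tiny):
        fac[tiny] = 1e-300
    logmat = np.log(fac)
    if sing_idx is not None:
        logmat[:, sing_idx] = np.log(1.0 - np.exp(sgn * 1j * u))
    lg = logmat @ beta.astype(complex)
    if sing_idx is not None:
        lg = lg - beta[sing_idx] * np.log(u)
    return np.exp(lg) * 1j * np.exp(1j * nodes)


def _half_panels(a: float, h: float, s: int):
    """Panel edges for the half-arc [a, a+h] with a singularity at ``a``:
    one Gauss-Jacobi head panel plus geometrically growing Legendre panels.
    Returns offsets [0, h*2^{1-s}, ..., h]."""
    return [0.0] + [h * 2.0 ** (j - s + 1) for j in range(s)]


def _arc_integrals(theta: np.ndarray, beta: np.ndarray, p: int = 8,
                   s: int = 1, kind: str = "abs") -> np.ndarray:
    """Integrals over every prevertex arc [theta_k, theta_{k+1}].

    kind="abs":     integral of |f'|/C  d(theta)   (image side lengths / C)
    kind="complex": integral of (f'/C) dz          (image side vectors / C)

    Each arc is split at its midpoint; each half uses a Gauss-Jacobi panel
    at its singular endpoint followed by ``s - 1`` geometrically growing
    Gauss-Legendre panels (one-half rule).
    """
    n = len(theta)
    th_ext = np.append(theta, theta[0] + TWO_PI)
    gaps = np.diff(th_ext)
    if np.any(gaps <= 0):
        raise MapFailureError("prevertex angles not strictly increasing")

    npanels = 2 * n * s
    nodes = np.empty((npanels, p))
    wts = np.empty((npanels, p))
    pref = np.empty(npanels)
    sing_beta = np.zeros(npanels)       # beta of the desingularised factor
    sing_u = np.ones((npanels, p))      # |node - singular endpoint|
    arc_of = np.empty(npanels, dtype=int)

    row = 0
    for k in range(n):
        a, b = th_ext[k], th_ext[k + 1]
        h = 0.5 * (b - a)
        edges = _half_panels(0.0, h, s)
        for side in (0, 1):  # 0: left half (sing at a), 1: right (sing at b)
            sing = k if side == 0 else (k + 1) % n
            origin = a if side == 0 else b
            sgn = 1.0 if side == 0 else -1.0
            for j in range(s):
                lo, hi = edges[j], edges[j + 1]
                if j == 0:
                    t, w = _gj_rule(p, _bkey(beta[sing]))
                    u = 0.5 * (1.0 + t) * hi
                    pref[row] = (0.5 * hi) ** (1.0 + beta[sing])
                    sing_beta[row] = beta[sing]
                    sing_u[row] = u
                else:
                    t, w = _gl_rule(p)
                    u = 0.5 * (lo + hi) + 0.5 * (hi - lo) * t
                    pref[row] = 0.5 * (hi - lo)
                nodes[row] = origin + sgn * u
                wts[row] = w
                arc_of[row] = k
                row += 1

    # Evaluate the log-product with the singular factor's angle difference
    # replaced by its analytic offset u (the rounded difference can hit 0).
    flat = nodes.ravel()
    # singular column index and half-side sign per panel row (-1: none)
    sc = np.full(npanels, -1, dtype=int)
    half_sgn = np.empty(npanels)
    row = 0
    for k in range(n):
        for side in (0, 1):
            sing = k if side == 0 else (k + 1) % n
            for j in range(s):
                if j == 0:
                    sc[row] = sing
                    half_sgn[row] = -1.0 if side == 0 else 1.0
                row += 1
    sing_rows = np.flatnonzero(sc >= 0)

    if kind == "abs":
        d = flat[:, None] - theta[None, :]
        # floor protects pathological trial configurations where a node of
        # one arc collides with another prevertex; real crowded solutions
        # keep nodes well above this scale
        logmat = np.log(np.maximum(np.abs(2.0 * np.sin(0.5 * d)), 1e-14))
        for r in sing_rows:
            logmat[r * p:(r + 1) * p, sc[r]] = np.log(
                2.0 * np.sin(0.5 * sing_u[r]))
        lg = (logmat @ beta).reshape(npanels, p)
        vals = np.exp(lg - sing_beta[:, None] * np.log(sing_u))
    else:
        d = theta[None, :] - flat[:, None]
        fac = 1.0 - np.exp(1j * d)
        tiny = np.abs(fac) < 1e-14
        if np.any(tiny):
            fac[tiny] = 1e-14
        logmat = np.log(fac)
        # left halves: node = origin + u -> factor 1 - e^{-iu};
        # right halves: node = origin - u -> factor 1 - e^{+iu}
        for r in sing_rows:
            logmat[r * p:(r + 1) * p, sc[r]] = np.log(
                1.0 - np.exp(half_sgn[r] * 1j * sing_u[r]))
        lg = (logmat @ beta.astype(complex)).reshape(npanels, p)
        vals = np.exp(lg - sing_beta[:, None] * np.log(sing_u)) \
            * 1j * np.exp(1j * nodes)
    panel_sums = pref * np.sum(wts * vals, axis=1)
    out = np.zeros(n, dtype=panel_sums.dtype)
    np.add.at(out, arc_of, panel_sums)
    return out


# ---------------------------------------------------------------------------
# the exterior map object
# ---------------------------------------------------------------------------

@dataclass
class ExteriorMap:
    """Numerical exterior Schwarz-Christoffel map.

    ``theta`` are the prevertex angles, strictly increasing with
    ``theta[0]`` in [0, 2*pi) (later entries may exceed 2*pi); they are
    aligned index-for-index with ``corners``.  ``C`` is real and positive:
    the canonical frame is rotated so the far-field wind is along +x in both
    domains, and ``C`` equals the conformal capacity of the polygon
    exterior.
    """

    theta: np.ndarray
    beta: np.ndarray
    C: float
    corners: np.ndarray
    residual: float
    crowded: bool = False
    quad: tuple = (12, 3)
    _c0: complex | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.theta)

    def to_json(self) -> str:
        """Serialize prevertices, exponents and constants (debugging aid)."""
        import json
        return json.dumps({
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "C": self.C,
            "corners_re": self.corners.real.tolist(),
            "corners_im": self.corners.imag.tolist(),
            "residual": self.residual,
            "crowded": self.crowded,
        })

    @classmethod
    def from_json(cls, s: str) -> "ExteriorMap":
        import json
        d = json.loads(s)
        return cls(theta=np.array(d["theta"]), beta=np.array(d["beta"]),
                   C=d["C"],
                   corners=np.array(d["corners_re"])
                   + 1j * np.array(d["corners_im"]),
                   residual=d["residual"], crowded=d["crowded"])

    @property
    def prevertex_points(self) -> np.ndarray:
        return np.exp(1j * self.theta)

    @property
    def capacity(self) -> float:
        """Conformal radius (logarithmic capacity) of the polygon exterior."""
        return self.C

    @property
    def side_lengths(self) -> np.ndarray:
        return np.abs(np.roll(self.corners, -1) - self.corners)

    # -- derivative and far field -----------------------------------------

    def fprime(self, zeta) -> np.ndarray:
        """f'(zeta) for |zeta| >= 1 (vectorised)."""
        z = np.asarray(zeta, dtype=complex)
        zk = self.prevertex_points
        lg = np.log(1.0 - zk / z[..., None]) @ self.beta.astype(complex)
        return self.C * np.exp(lg)

    @property
    def farfield_offset(self) -> complex:
        """c0 in the expansion f(zeta) = C*zeta + c0 + O(1/zeta)."""
        if self._c0 is None:
            zbig = 80.0 * np.exp(1j * 0.37)
            self._c0 = complex(self.forward(zbig) - self.C * zbig)
        return self._c0

    # -- boundary geometry helpers -----------------------------------------

    def _gaps(self) -> np.ndarray:
        th_ext = np.append(self.theta, self.theta[0] + TWO_PI)
        return np.diff(th_ext)

    def side_quad(self, k: int, p: int = 12, s: int = 4) -> "_SideQuad":
        return _SideQuad(self, k, p=p, s=s)

    # -- forward map --------------------------------------------------------

    def forward(self, zeta):
        """Image of canonical point(s) *zeta* (|zeta| >= 1)."""
        z = np.atleast_1d(np.asarray(zeta, dtype=complex))
        out = np.empty_like(z)
        for i, zi in enumerate(z.ravel()):
            out.ravel()[i] = self._forward_one(zi)
        if np.isscalar(zeta) or np.asarray(zeta).ndim == 0:
            return complex(out.ravel()[0])
        return out

    def _forward_one(self, zeta: complex) -> complex:
        rho = abs(zeta)
        if rho < 1.0 - 1e-9:
            raise ValueError(f"|zeta| = {rho} < 1 is outside the domain")
        rho = max(rho, 1.0)
        ang = float(np.angle(zeta))
        # anchor: prevertex nearest in angle
        d = np.angle(np.exp(1j * (ang - self.theta)))
        k = int(np.argmin(np.abs(d)))
        if rho < 1.0 + 1e-13 and abs(d[k]) < 1e-13:
            return complex(self.corners[k])
        val = complex(self.corners[k])
        if rho > 1.0 + 1e-13:
            val = val + self.C * self._radial_leg(k, rho)
        th_target = self.theta[k] + d[k]
        if abs(d[k]) > 1e-15:
            if rho > 1.0 + 1e-13:
                val = val + self.C * self._arc_leg(rho, self.theta[k], th_target)
            else:
                # on the unit circle: integrate along the boundary arc
                sq = self.side_quad(k if d[k] > 0 else (k - 1) % self.n)
                if d[k] > 0:
                    slen = sq.arclength(th_target)
                    c0 = self.corners[k]
                    c1 = self.corners[(k + 1) % self.n]
                    return complex(c0 + slen / abs(c1 - c0) * (c1 - c0))
                km = (k - 1) % self.n
                gap = (self.theta[k] - self.theta[km]) % TWO_PI
                slen = sq.arclength(self.theta[km] + gap + d[k])
                c0 = self.corners[km]
                c1 = self.corners[k]
                return complex(c0 + slen / abs(c1 - c0) * (c1 - c0))
        return complex(val)

    def _radial_leg(self, k: int, rho: float, p: int = 14) -> complex:
        """integral of f'/C along the ray t*z_k, t in [1, rho]."""
        beta_k = self.beta[k]
        zk = np.exp(1j * self.theta[k])
        gaps = self._gaps()
        gnear = min(gaps[k], gaps[(k - 1) % self.n])
        total = 0.0 + 0.0j
        span = rho - 1.0
        l0 = min(max(gnear, 1e-14), span)
        # Gauss-Jacobi head on [1, 1+l0]
        t, w = _gj_rule(p, _bkey(beta_k))
        u = 0.5 * (1.0 + t) * l0
        tt = 1.0 + u
        logmat = np.log(1.0 - np.exp(1j * self.theta) / (tt[:, None] * zk))
        # factor k is (1 - 1/t) = u / (1 + u): use the analytic offset
        logmat[:, k] = np.log(u) - np.log1p(u)
        lg = logmat @ self.beta.astype(complex)
        g = np.exp(lg - beta_k * np.log(u)) * zk
        total += (0.5 * l0) ** (1.0 + beta_k) * np.dot(w, g)
        # geometric Legendre panels
        lo = 1.0 + l0
        t, w = _gl_rule(p)
        while lo < rho - 1e-15:
            hi = min(rho, lo + (lo - 1.0))
            tt = 0.5 * (lo + hi) + 0.5 * (hi - lo) * t
            lg = np.log(1.0 - np.exp(1j * self.theta) / (tt[:, None] * zk)) \
                @ self.beta.astype(complex)
            total += 0.5 * (hi - lo) * np.dot(w, np.exp(lg) * zk)
            lo = hi
        return total

    def _arc_leg(self, rho: float, th_from: float, th_to: float,
                 p: int = 14) -> complex:
        """integral of f'/C along the circle of radius rho between angles."""
        if th_to == th_from:
            return 0.0 + 0.0j
        t, w = _gl_rule(p)
        total = 0.0 + 0.0j
        # adaptive bisection: panel ok when its arc length is below its
        # distance to the nearest prevertex (all at radius 1)
        stack = [(min(th_from, th_to), max(th_from, th_to), 0)]
        sign = 1.0 if th_to > th_from else -1.0
        while stack:
            lo, hi, depth = stack.pop()
            mids = 0.5 * (lo + hi)
            dang = np.abs(np.angle(np.exp(1j * (mids - self.theta))))
            dist = float(np.sqrt((rho - 1.0) ** 2
                                 + (rho * dang) ** 2).min())
            if depth < 40 and rho * (hi - lo) > max(dist, 1e-14):
                stack.append((lo, mids, depth + 1))
                stack.append((mids, hi, depth + 1))
                continue
            tt = 0.5 * (lo + hi) + 0.5 * (hi - lo) * t
            zz = rho * np.exp(1j * tt)
            lg = np.log(1.0 - np.exp(1j * self.theta) / zz[:, None]) \
                @ self.beta.astype(complex)
            total += 0.5 * (hi - lo) * np.dot(w, np.exp(lg) * 1j * zz)
        return sign * total

    def forward_polar_grid(self, r: np.ndarray, theta: np.ndarray,
                           p: int = 8) -> np.ndarray:
        """Images of the polar tensor grid ``r x theta`` (|zeta| >= 1).

        Much faster than pointwise :meth:`forward`: boundary values are
        computed per angle by side-arclength evaluation, then the map is
        marched outward in radius with Gauss-Legendre steps shared across
        all angles.  The first radial interval is subdivided geometrically
        because f' is singular at the prevertices on the unit circle.
        """
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if r[0] < 1.0 - 1e-12:
            raise ValueError("radial grid must start at or outside r = 1")
        nt = len(theta)
        out = np.empty((len(r), nt), dtype=complex)

        # boundary row: f(e^{i theta}) via the side arclength functions
        th0 = np.mod(theta - self.theta[0], TWO_PI) + self.theta[0]
        th_ext = np.append(self.theta, self.theta[0] + TWO_PI)
        side = np.clip(np.searchsorted(th_ext, th0, side="right") - 1,
                       0, self.n - 1)
        bvals = np.empty(nt, dtype=complex)
        for k in np.unique(side):
            sq = self.side_quad(int(k))
            c0 = self.corners[k]
            c1 = self.corners[(k + 1) % self.n]
            u = (c1 - c0) / abs(c1 - c0)
            for j in np.flatnonzero(side == k):
                bvals[j] = c0 + u * sq.arclength(float(th0[j]))
        row = bvals
        if abs(r[0] - 1.0) < 1e-12:
            out[0] = row
            start = 1
        else:
            start = 0
            row = row + self._march(1.0, r[0], theta, p, split=6)
            out[0] = row
        prev_r = r[0] if start == 0 else 1.0
        for i in range(start, len(r)):
            lo, hi = prev_r, r[i]
            if hi > lo:
                splits = 6 if lo < 1.0 + 1e-9 else 1
                row = row + self._march(lo, hi, theta, p, split=splits)
            out[i] = row
            prev_r = hi
        return out

    def _march(self, lo: float, hi: float, theta: np.ndarray, p: int,
               split: int = 1) -> np.ndarray:
        """integral of f' dz along rays at each angle, r from lo to hi,
        with *split* geometric subintervals refined toward lo."""
        t_gl, w_gl = _gl_rule(p)
        edges = lo + (hi - lo) * (2.0 ** np.arange(split + 1) - 1) \
            / (2.0 ** split - 1) if split > 1 else np.array([lo, hi])
        total = np.zeros(len(theta), dtype=complex)
        eith = np.exp(1j * theta)
        for a, b in zip(edges[:-1], edges[1:]):
            rr = 0.5 * (a + b) + 0.5 * (b - a) * t_gl    # (p,)
            zz = rr[None, :] * eith[:, None]             # (nt, p)
            fp = self.fprime(zz)
            total += 0.5 * (b - a) * (fp @ w_gl) * eith
        return total

    # -- inverse map --------------------------------------------------------

    def inverse(self, z, tol: float = TOL_INV, maxiter: int = 50):
        """Preimage of physical point(s) *z* (outside or on the polygon)."""
        arr = np.atleast_1d(np.asarray(z, dtype=complex))
        out = np.empty_like(arr)
        for i, zi in enumerate(arr.ravel()):
            out.ravel()[i] = self._inverse_one(zi, tol, maxiter)
        if np.isscalar(z) or np.asarray(z).ndim == 0:
            return complex(out.ravel()[0])
        return out

    def _nearest_boundary(self, z: complex):
        """(side index, clamped parameter t, distance) of the closest
        polygon side to *z*."""
        a = self.corners
        b = np.roll(self.corners, -1)
        e = b - a
        t = np.clip(((z - a) / e).real, 0.0, 1.0)
        proj = a + t * e
        d = np.abs(z - proj)
        k = int(np.argmin(d))
        return k, float(t[k]), float(d[k])

    def _boundary_seed(self, z: complex) -> complex:
        """Seed Newton from the preimage of the boundary projection of z."""
        k, t, d = self._nearest_boundary(z)
        sq = self.side_quad(k)
        th = float(sq.invert(np.array([t * self.side_lengths[k]]))[0])
        zeta0 = np.exp(1j * th)
        fp = abs(self.fprime(zeta0 * (1.0 + 1e-9)))
        return zeta0 * (1.0 + max(d / max(fp, 1e-12), 1e-12))

    def _newton(self, z, zeta, tol, maxiter, scale):
        err = np.inf
        for _ in range(maxiter):
            fz = self._forward_one(zeta)
            err = fz - z
            if abs(err) < tol * scale:
                return zeta
            step = err / self.fprime(zeta)
            znew = zeta - step
            r = abs(znew)
            if r < 1.0:
                znew = znew / r ** 2  # reflect across the unit circle
                if abs(znew) > abs(zeta) + 2.0:  # wild reflection: damp
                    znew = zeta - 0.3 * step
            zeta = znew
        raise InverseFailureError(
            f"Newton failed for z={z} (last |f-z|={abs(err):.2e})")

    def _inverse_one(self, z: complex, tol: float, maxiter: int,
                     seed: complex | None = None) -> complex:
        scale = max(1.0, abs(z))
        k, t, dist = self._nearest_boundary(z)
        if dist < 1e-9 * scale:
            # on the polygon: 1-D inversion of the side arclength
            sq = self.side_quad(k)
            th = float(sq.invert(np.array([t * self.side_lengths[k]]))[0])
            return np.exp(1j * th)
        if seed is None:
            if dist < 0.25:
                seed = self._boundary_seed(z)
            else:
                seed = (z - self.farfield_offset) / self.C
            if abs(seed) < 1.0 + 1e-12:
                seed = seed / abs(seed) * (1.0 + 1e-9) \
                    if abs(seed) > 0 else 1.0 + 1e-9
        try:
            return self._newton(z, seed, tol, maxiter, scale)
        except InverseFailureError:
            # retry once from the boundary-projection seed
            return self._newton(z, self._boundary_seed(z), tol, maxiter,
                                scale)

    def boundary_preimage_angle(self, side: int, arclength: float) -> float:
        """Angle on the unit circle of the boundary point at *arclength*
        from corner *side* along side *side*."""
        sq = self.side_quad(side)
        return sq.invert(np.array([arclength]))[0]


class _SideQuad:
    """Cumulative image arclength along one prevertex arc.

    Used to pull physical boundary points (penguins, midpoints) back to the
    unit circle by solving ``s(theta) = target`` with monotone bracketing.
    """

    def __init__(self, emap: ExteriorMap, k: int, p: int = 12, s: int = 4):
        self.emap = emap
        self.k = k
        self.p = p
        th_ext = np.append(emap.theta, emap.theta[0] + TWO_PI)
        self.a = th_ext[k]
        self.b = th_ext[k + 1]
        self.beta_a = emap.beta[k]
        self.beta_b = emap.beta[(k + 1) % emap.n]
        h = 0.5 * (self.b - self.a)
        offs = _half_panels(0.0, h, s)
        edges = [self.a + o for o in offs] + \
                [self.b - o for o in reversed(offs[:-1])]
        self.edges = np.array(edges)
        kinds = (["gj_left"] + ["gl"] * (s - 1)
                 + ["gl"] * (s - 1) + ["gj_right"])
        self.kinds = kinds
        vals = [self._panel_full(i) for i in range(len(kinds))]
        self.cum = np.concatenate([[0.0], np.cumsum(vals)])

    # panel integrals ------------------------------------------------------

    def _gj_partial(self, origin, beta, sing_idx, lo_u, hi_u):
        """integral of u^beta * G over u in [lo_u, hi_u] measured from the
        singular endpoint at *origin* (lo_u = 0 allowed)."""
        emap, p = self.emap, self.p
        sgn = 1.0 if origin == self.a else -1.0

        def piece(up):
            if up <= 0:
                return 0.0
            t, w = _gj_rule(p, _bkey(beta))
            u = 0.5 * (1.0 + t) * up
            nodes = origin + sgn * u
            g = _integrand_abs(nodes, emap.theta, emap.beta, sing_idx, u)
            return (0.5 * up) ** (1.0 + beta) * float(np.dot(w, g))

        return piece(hi_u) - piece(lo_u)

    def _gl(self, lo, hi):
        if hi <= lo:
            return 0.0
        t, w = _gl_rule(self.p)
        nodes = 0.5 * (lo + hi) + 0.5 * (hi - lo) * t
        g = _integrand_abs(nodes, self.emap.theta, self.emap.beta)
        return 0.5 * (hi - lo) * float(np.dot(w, g))

    def _panel_full(self, i):
        lo, hi = self.edges[i], self.edges[i + 1]
        kind = self.kinds[i]
        if kind == "gj_left":
            return self._gj_partial(self.a, self.beta_a,
                                    self.k, 0.0, hi - self.a)
        if kind == "gj_right":
            return self._gj_partial(self.b, self.beta_b,
                                    (self.k + 1) % self.emap.n,
                                    0.0, self.b - lo)
        return self._gl(lo, hi)

    def _partial_in_panel(self, i, x):
        lo = self.edges[i]
        kind = self.kinds[i]
        if kind == "gj_left":
            return self._gj_partial(self.a, self.beta_a, self.k,
                                    lo - self.a, x - self.a)
        if kind == "gj_right":
            # integrate in u = b - theta: theta in [lo, x] <-> u in [b-x, b-lo]
            return self._gj_partial(self.b, self.beta_b,
                                    (self.k + 1) % self.emap.n,
                                    self.b - x, self.b - lo)
        return self._gl(lo, x)

    # public API -----------------------------------------------------------

    @property
    def total(self) -> float:
        """Image length of the full arc divided by C."""
        return float(self.cum[-1])

    def arclength(self, theta: float) -> float:
        """Image arclength from corner k to boundary angle *theta*."""
        x = float(np.clip(theta, self.a, self.b))
        i = int(np.searchsorted(self.edges, x, side="right") - 1)
        i = min(max(i, 0), len(self.kinds) - 1)
        return self.emap.C * (self.cum[i] + self._partial_in_panel(i, x))

    def invert(self, targets: np.ndarray) -> np.ndarray:
        """Angles theta with arclength(theta) = target, per target."""
        side_len = self.emap.C * self.total
        out = np.empty(len(targets))
        for j, sj in enumerate(targets):
            sj = float(np.clip(sj, 0.0, side_len))
            cum_s = self.emap.C * self.cum
            i = int(np.searchsorted(cum_s, sj, side="right") - 1)
            i = min(max(i, 0), len(self.kinds) - 1)
            lo, hi = self.edges[i], self.edges[i + 1]
            f = lambda x: self.emap.C * (self.cum[i]
                                         + self._partial_in_panel(i, x)) - sj
            flo, fhi = f(lo), f(hi)
            if flo >= 0.0:
                out[j] = lo
            elif fhi <= 0.0:
                out[j] = hi
            else:
                out[j] = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-15)
        return out


# ---------------------------------------------------------------------------
# parameter problem
# ---------------------------------------------------------------------------

def polygon_turning(corners: np.ndarray) -> np.ndarray:
    """Turning parameters beta_k = tau_k / pi at each corner (sum = 2)."""
    edges = np.roll(corners, -1) - corners
    prev = np.roll(edges, 1)
    tau = np.angle(edges / prev)
    beta = tau / np.pi
    if abs(beta.sum() - 2.0) > 1e-8:
        raise ValueError(f"turning angles sum to {beta.sum()} * pi != 2 * pi"
                         " -- polygon not simple CCW?")
    return beta


def _theta_from_x(x: np.ndarray) -> np.ndarray:
    """Map unconstrained log-gap variables to prevertex angles.

    gaps proportional to (exp(x_1), ..., exp(x_{n-1}), 1), theta_0 = 0.
    Variables are clipped to +/-60 so that wild root-finder trial steps
    cannot overflow; the representable gap-ratio range stays astronomical.
    """
    e = np.append(np.exp(np.clip(x, -60.0, 60.0)), 1.0)
    gaps = TWO_PI * e / e.sum()
    # floor so that accumulated angles remain strictly increasing in floats
    gaps = np.maximum(gaps, 1e-12)
    gaps *= TWO_PI / gaps.sum()
    return np.concatenate([[0.0], np.cumsum(gaps[:-1])])


def _x_from_gaps(gaps: np.ndarray) -> np.ndarray:
    g = np.maximum(np.asarray(gaps, float), 1e-14)
    return np.log(g[:-1] / g[-1])


def _residual(x, beta, ell, p, s):
    theta = _theta_from_x(x)
    n = len(theta)
    S = np.exp(1j * theta) @ beta.astype(complex)
    res = [S.real, S.imag]
    if n > 3:
        I = _arc_integrals(theta, beta, p=p, s=s, kind="abs")
        res_side = np.log(I[1:n - 2] / I[0]) - np.log(ell[1:n - 2] / ell[0])
        res = list(res_side) + res
    return np.array(res)


def _default_gaps(ell: np.ndarray) -> np.ndarray:
    """Initial guess: gaps proportional to physical side lengths."""
    g = ell / ell.sum() * TWO_PI
    return np.maximum(g, 1e-4)


def _davis_gaps(gaps: np.ndarray, beta: np.ndarray, ell: np.ndarray,
                iters: int = 60, gamma: float = 0.8) -> np.ndarray:
    """Fixed-point sweeps nudging each gap toward its side-length share.

    A multiplicative update in the spirit of Davis' iteration for SC
    parameter problems: cheap, globally stable, and an excellent seed for
    the Newton-type solve even for very irregular many-cornered polygons.
    """
    ellhat = ell / ell.sum()
    for _ in range(iters):
        theta = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        I = _arc_integrals(theta, beta, p=8, s=1, kind="abs")
        gaps = gaps * (ellhat / (I / I.sum())) ** gamma
        gaps = np.maximum(gaps, 1e-10)
        gaps *= TWO_PI / gaps.sum()
    return gaps


def _warm_start_gaps(warm: ExteriorMap, corners: np.ndarray) -> np.ndarray:
    """Gaps guessed by matching each new corner to the nearest old corner."""
    th = []
    for w in corners:
        j = int(np.argmin(np.abs(warm.corners - w)))
        th.append(warm.theta[j])
    th = np.unwrap(np.array(th) - warm.theta[0]) + warm.theta[0]
    # force strict cyclic increase
    for i in range(1, len(th)):
        if th[i] <= th[i - 1]:
            th[i] = th[i - 1] + 1e-5
    gaps = np.diff(np.append(th, th[0] + TWO_PI))
    if gaps[-1] <= 0:
        return _default_gaps(np.abs(np.roll(corners, -1) - corners))
    return gaps / gaps.sum() * TWO_PI


def solve_parameter_problem(poly: ScaledPolygon,
                            warm_start: ExteriorMap | None = None,
                            tol_map: float = TOL_MAP,
                            gap_min: float = GAP_MIN) -> ExteriorMap:
    """Solve the exterior SC parameter problem for a scaled polygon.

    The nonlinear system (side-length ratios + closure) is solved by a
    quasi-Newton root finder in log-gap variables with ``theta_0`` gauge
    fixed; quadrature order is escalated until the vertex-image residual
    stabilises below ``tol_map`` (or a :class:`MapFailureError` is raised).
    On success the canonical frame is rotated so that C is real positive.
    """
    corners = np.asarray(poly.corners, dtype=complex)
    n = len(corners)
    if n < 3:
        raise ValueError("need at least 3 polygon corners")
    beta = polygon_turning(corners)
    ell = np.abs(np.roll(corners, -1) - corners)

    if warm_start is not None and warm_start.n == n:
        inits = [_warm_start_gaps(warm_start, corners), None]  # None: davis
    else:
        inits = [None]

    best = None
    for gaps0 in inits:
        if gaps0 is None:
            gaps0 = _davis_gaps(_default_gaps(ell), beta, ell)
        x0 = _x_from_gaps(gaps0)
        for (p, s) in ((8, 1), (12, 2), (16, 3)):
            sol = optimize.root(_residual, x0, args=(beta, ell, p, s),
                                method="hybr", options={"xtol": 1e-12})
            x = sol.x
            rnorm = float(np.max(np.abs(_residual(x, beta, ell, p, s))))
            if rnorm > 1e-8:
                ls = optimize.least_squares(
                    _residual, x, args=(beta, ell, p, s),
                    method="lm" if n > 3 else "trf", xtol=1e-14, ftol=1e-14)
                if np.max(np.abs(ls.fun)) < rnorm:
                    x = ls.x
                    rnorm = float(np.max(np.abs(ls.fun)))
            theta = _theta_from_x(x)
            # high-order complex side integrals -> constants and residual
            J = _arc_integrals(theta, beta, p=p + 4, s=s + 1, kind="complex")
            C = (corners[1] - corners[0]) / J[0]
            images = corners[0] + C * np.concatenate([[0.0],
                                                      np.cumsum(J[:-1])])
            vres = float(np.max(np.abs(images - corners)))
            if best is None or vres < best[0]:
                best = (vres, theta, C, (p + 4, s + 1))
            x0 = x
            if vres < tol_map:
                break
        if best[0] < tol_map:
            break

    vres, theta, C, quad = best
    if vres > TOL_FAIL:
        raise MapFailureError(
            f"SC parameter problem failed (vertex residual {vres:.2e})",
            residual=vres)

    gaps = np.diff(np.append(theta, theta[0] + TWO_PI))
    crowded = bool(np.min(gaps) < gap_min)
    if crowded:
        warnings.warn(
            f"prevertex crowding: min gap {np.min(gaps):.2e} rad",
            CrowdingWarning, stacklevel=2)

    # rotate the canonical frame so that C is real positive (wind along +x)
    alpha = float(np.angle(C))
    theta = theta + alpha
    if theta[0] < 0:
        theta = theta + TWO_PI
    elif theta[0] >= TWO_PI:
        theta = theta - TWO_PI
    return ExteriorMap(theta=theta, beta=beta, C=float(np.abs(C)),
                       corners=corners, residual=vres, crowded=crowded,
                       quad=quad)


# ---------------------------------------------------------------------------
# canonical flow
# ---------------------------------------------------------------------------

def complex_potential(zeta):
    """Joukowsky potential F(zeta) = zeta + 1/zeta (uniform flow past the
    unit disk, far-field speed 1 along +x)."""
    z = np.asarray(zeta, dtype=complex)
    return z + 1.0 / z


def canonical_velocity(zeta):
    """Polar velocity components (u_r, u_theta) of the canonical flow.

    dF/dzeta = 1 - 1/zeta**2 gives the Cartesian conjugate velocity; on the
    unit circle the radial component vanishes (the disk is a streamline) and
    the stagnation points sit at zeta = +/-1.
    """
    z = np.asarray(zeta, dtype=complex)
    w = 1.0 - 1.0 / z ** 2       # u - i v
    u, v = w.real, -w.imag
    th = np.angle(z)
    u_r = u * np.cos(th) + v * np.sin(th)
    u_t = -u * np.sin(th) + v * np.cos(th)
    return u_r, u_t


def canonical_velocity_polar_grid(r: np.ndarray, theta: np.ndarray):
    """(u_r, u_theta) on the tensor grid r x theta, from the potential
    phi = (r + 1/r) cos(theta)."""
    rr = r[:, None]
    tt = theta[None, :]
    u_r = (1.0 - 1.0 / rr ** 2) * np.cos(tt)
    u_t = -(1.0 + 1.0 / rr ** 2) * np.sin(tt)
    return u_r, u_t
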