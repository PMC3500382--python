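"""Independent physical-domain advection-diffusion oracle.

Solves the steady advection-diffusion equation directly on a Cartesian grid
around the (scaled) huddle polygon -- no annulus, no conformal invariance --
and compares against the canonical-domain solution mapped forward through
the Schwarz-Christoffel transformation.

The outward flux density diverges like d**(-1/3) at convex polygon corners,
so no finite-probe estimate can reproduce the exact per-penguin arc
integrals; instead both routes are probed with the *same* two-point normal
gradient at the same physical locations, which isolates what the oracle is
meant to test: the conformal map, the conformal invariance of the
transport equation, and the annulus solver.
"""

import numpy as np
from matplotlib.path import Path
from scipy import sparse
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.sparse.linalg import spsolve


def _forward_cloud(emap, R):
    """Forward-mapped polar cloud with canonical coordinates attached."""
    r_cloud = np.concatenate([
        1.0 + np.geomspace(1e-4, 0.2, 25),
        np.linspace(1.22, R + 0.4, 70),
    ])
    th_cloud = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    Z = emap.forward_polar_grid(r_cloud, th_cloud)
    return r_cloud, th_cloud, Z


def solve_physical(emap, poly, Pe, R, h=0.035):
    """Direct Cartesian FD solve of Pe u.grad T = lap T outside the polygon.

    Returns a callable T(points (n,2)).  Velocity and the outer isotherm
    (image of |zeta| = R) come from the forward-mapped cloud; the PDE is
    discretised and solved entirely in the physical plane.
    """
    r_cloud, th_cloud, Z = _forward_cloud(emap, R)
    zeta = r_cloud[:, None] * np.exp(1j * th_cloud[None, :])
    w = (1.0 - 1.0 / zeta ** 2) / emap.fprime(zeta)   # u - i v
    pts = np.column_stack([Z.real.ravel(), Z.imag.ravel()])
    interp_u = LinearNDInterpolator(pts, w.real.ravel(), fill_value=0.0)
    interp_v = LinearNDInterpolator(pts, (-w.imag).ravel(), fill_value=0.0)
    interp_rz = LinearNDInterpolator(pts, np.broadcast_to(
        r_cloud[:, None], Z.shape).ravel(), fill_value=R + 1.0)

    extent = np.abs(Z[-1]).max() + 2 * h
    x = np.arange(-extent, extent + h, h)
    y = np.arange(-extent, extent + h, h)
    X, Y = np.meshgrid(x, y, indexing="ij")
    nx, ny = X.shape
    flat = np.column_stack([X.ravel(), Y.ravel()])

    verts = np.column_stack([poly.vertices.real, poly.vertices.imag])
    inside = Path(verts).contains_points(flat).reshape(nx, ny)
    rz = interp_rz(flat).reshape(nx, ny)
    outer = (~inside) & (rz >= R)
    U = interp_u(flat).reshape(nx, ny)
    V = interp_v(flat).reshape(nx, ny)

    idx = np.arange(nx * ny).reshape(nx, ny)
    free = ~(inside | outer)
    fi, fj = np.nonzero(free)
    assert fi.min() > 0 and fi.max() < nx - 1
    assert fj.min() > 0 and fj.max() < ny - 1

    rows, cols, data = [], [], []
    b = np.zeros(nx * ny)
    d1, d0 = idx[inside], idx[outer]
    rows.extend(d1); cols.extend(d1); data.extend(np.ones(len(d1)))
    b[d1] = 1.0
    rows.extend(d0); cols.extend(d0); data.extend(np.ones(len(d0)))
    c = idx[fi, fj]
    for di, dj, coef in [
        (0, 0, -4.0 / h ** 2 * np.ones(len(fi))),
        (1, 0, 1.0 / h ** 2 - Pe * U[fi, fj] / (2 * h)),
        (-1, 0, 1.0 / h ** 2 + Pe * U[fi, fj] / (2 * h)),
        (0, 1, 1.0 / h ** 2 - Pe * V[fi, fj] / (2 * h)),
        (0, -1, 1.0 / h ** 2 + Pe * V[fi, fj] / (2 * h)),
    ]:
        rows.extend(c)
        cols.extend(idx[fi + di, fj + dj])
        data.extend(np.broadcast_to(coef, (len(fi),)))
    A = sparse.csr_matrix((data, (rows, cols)),
                          shape=(nx * ny, nx * ny)).tocsc()
    T = spsolve(A, b).reshape(nx, ny)
    grid_interp = RegularGridInterpolator((x, y), T)

    def evaluate(points):
        return grid_interp(points)

    return evaluate


def canonical_evaluator(emap, grid, R):
    """T(points) from the annulus solution pushed through the forward map."""
    r_cloud, th_cloud, Z = _forward_cloud(emap, R)
    ann = RegularGridInterpolator(
        (grid.r, np.append(grid.theta, 2 * np.pi)),
        np.column_stack([grid.T, grid.T[:, :1]]),
        bounds_error=False, fill_value=None)
    rr, tt = np.meshgrid(r_cloud, th_cloud, indexing="ij")
    vals = ann(np.column_stack([np.clip(rr.ravel(), 1.0, grid.R),
                                tt.ravel()]))
    pts = np.column_stack([Z.real.ravel(), Z.imag.ravel()])
    interp = LinearNDInterpolator(pts, vals, fill_value=0.0)

    def evaluate(points):
        return interp(points)

    return evaluate


def probe_profile(evaluate, poly, delta=0.07, n_sub=12):
    """Per-penguin boundary heat loss from a two-probe normal gradient.

    flux ~ (T(p + delta n) - T(p + 2 delta n)) / delta, sampled along each
    penguin's share of the polygon (midpoint to midpoint through its
    vertex) and integrated with the midpoint rule.
    """
    v = poly.vertices
    nb = len(v)
    q = np.zeros(nb)
    for i in range(nb):
        for (a, bpt) in ((0.5 * (v[i - 1] + v[i]), v[i]),
                         (v[i], 0.5 * (v[i] + v[(i + 1) % nb]))):
            e = bpt - a
            n_out = -1j * e / abs(e)
            ts = (np.arange(n_sub) + 0.5) / n_sub
            seg = a + ts * e
            p1 = seg + delta * n_out
            p2 = seg + 2.0 * delta * n_out
            T1 = evaluate(np.column_stack([p1.real, p1.imag]))
            T2 = evaluate(np.column_stack([p2.real, p2.imag]))
            q[i] += np.sum((T1 - T2) / delta) * abs(e) / n_sub
    return q
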