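"""Shape, motion and fairness metrics of simulated huddles.

Width and length are axis-aligned extents (the wind blows along +x),
measured centre-to-centre plus one lattice unit so a single row has width
one penguin.  The waiting-time statistics quantify how evenly the burden of
facing the wind is shared: with N penguins and one relocation per
iteration, perfectly even sharing gives every penguin a normalized waiting
time (gap between its successive relocations, divided by N) of one, while
choosing the mover uniformly at random gives geometric waiting times with
normalized mean 1 and standard deviation sqrt(1 - 1/N) ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import thermal
from .dynamics import SimConfig, Trajectory, run_simulation
from .lattice import Huddle, cartesian_xy


class DiagnosticsError(Exception):
    pass


@dataclass(frozen=True)
class ShapeMetrics:
    length: float              # extent along the wind (x)
    width: float               # extent across the wind (y)
    aspect_ratio: float
    aspect_ratio_core: float   # after protuberance exclusion
    centroid: tuple


@dataclass(frozen=True)
class WaitingStats:
    intervals: np.ndarray      # pooled per-penguin gaps / N
    mean: float
    sd: float


def shape_metrics(huddle: Huddle,
                  exclude_protuberances: bool = False) -> ShapeMetrics:
    """Bounding-box extents along/across the wind.

    Protuberance exclusion keeps only penguins with at least three occupied
    neighbours (the simplest filter that removes one-penguin-wide chains);
    with exclusion on, ``length``/``width`` are measured over that core.
    """
    xy = cartesian_xy(huddle.sites)
    core_sites = [s for s in huddle.sites if huddle.neighbor_count(s) >= 3]
    core_xy = cartesian_xy(core_sites) if core_sites else xy

    def extents(a):
        return (a[:, 0].max() - a[:, 0].min() + 1.0,
                a[:, 1].max() - a[:, 1].min() + 1.0)

    l_raw, w_raw = extents(xy)
    l_core, w_core = extents(core_xy)
    ar_core = l_core / w_core
    if exclude_protuberances:
        length, width = l_core, w_core
    else:
        length, width = l_raw, w_raw
    return ShapeMetrics(length=float(length), width=float(width),
                        aspect_ratio=float(length / width),
                        aspect_ratio_core=float(ar_core),
                        centroid=(float(xy[:, 0].mean()),
                                  float(xy[:, 1].mean())))


def steady_state_iteration(widths: np.ndarray, window: int):
    """First iteration after which the width stays constant for *window*
    consecutive iterations; ``None`` when never reached.

    ``widths[k]`` is the across-wind width after iteration k+1.
    """
    w = np.asarray(widths, dtype=float)
    if len(w) < window or window < 1:
        return None
    changed = np.abs(np.diff(w)) > 1e-9
    # run_len[k]: number of consecutive unchanged steps starting at k
    run_len = np.zeros(len(w), dtype=int)
    count = 0
    for i in range(len(w) - 1, 0, -1):
        count = 0 if changed[i - 1] else count + 1
        run_len[i - 1] = count
    for k in range(len(w) - window + 1):
        if run_len[k] >= window - 1:
            return int(k)
    return None


def drift_speed(trajectory: Trajectory, start: int | None = None) -> float:
    """Downwind drift: slope of the centroid x-coordinate per iteration,
    fitted over the steady-state window (default: from the steady-state
    iteration, or the last half of the run)."""
    cx = trajectory.centroid_x
    if start is None:
        n = trajectory.config.n
        start = steady_state_iteration(trajectory.widths, 2 * n)
        if start is None:
            start = len(cx) // 2
    seg = cx[start:]
    if len(seg) < 2:
        raise DiagnosticsError("steady window too short for a drift fit")
    return float(np.polyfit(np.arange(len(seg)), seg, 1)[0])


def waiting_time_stats(movers, N: int | None = None,
                       min_relocations: int = 2,
                       coverage: float = 0.8) -> WaitingStats:
    """Pooled normalized waiting times between successive relocations.

    *movers* is a Trajectory or a sequence of per-iteration mover ids.
    Censored intervals (before a penguin's first and after its last
    relocation) are excluded.  Raises when fewer than *coverage* of the N
    penguins relocated at least *min_relocations* times.
    """
    if isinstance(movers, Trajectory):
        ids = movers.mover_ids()
        N = movers.config.n
    else:
        ids = np.asarray(movers, dtype=int)
        if N is None:
            raise ValueError("N required when passing a raw mover sequence")
    when: dict[int, list] = {}
    for it, pid in enumerate(ids):
        when.setdefault(int(pid), []).append(it)
    n_ok = sum(1 for v in when.values() if len(v) >= min_relocations)
    if n_ok < coverage * N:
        raise DiagnosticsError(
            f"only {n_ok}/{N} penguins relocated >= {min_relocations} "
            f"times (need {coverage:.0%}); run longer")
    gaps = []
    for v in when.values():
        if len(v) >= 2:
            gaps.extend(np.diff(v))
    gaps = np.asarray(gaps, dtype=float) / N
    return WaitingStats(intervals=gaps, mean=float(gaps.mean()),
                        sd=float(gaps.std(ddof=1)))


def random_mover_baseline(N: int, steps: int,
                          rng: np.random.Generator | int = 0) -> WaitingStats:
    """Waiting-time statistics when the mover is uniformly random.

    The reference against which the model's fairness is judged: geometric
    waiting times, normalized mean 1 and sd sqrt(1 - 1/N).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = rng.integers(0, N, size=steps)
    return waiting_time_stats(ids, N=N)


def width_vs_peclet(N: int, pe_values, seed: int = 0,
                    max_iter: int | None = None,
                    r_outer: float = thermal.DEFAULT_R,
                    window: int | None = None) -> pd.DataFrame:
    """Steady-state width for each Péclet number (deterministic runs).

    Each run starts from the same seeded initial huddle, uses a grid
    resolution adequate for its Pe, and reports the width and aspect ratio
    averaged over the final *window* (default 2N) iterations.
    """
    if max_iter is None:
        max_iter = 300 + 2 * N
    if window is None:
        window = 2 * N
    rows = []
    for pe in pe_values:
        n_r, n_theta = thermal.suggested_grid(pe, r_outer)
        cfg = SimConfig(n=N, pe=float(pe), r_outer=r_outer, eps=0.0,
                        seed=seed, max_iter=max_iter, n_r=n_r,
                        n_theta=n_theta, record_every=max_iter)
        traj = run_simulation(cfg)
        w = float(traj.widths[-window:].mean())
        l = float(traj.lengths[-window:].mean())
        k = steady_state_iteration(traj.widths, window)
        rows.append({"N": N, "Pe": float(pe), "width": w, "length": l,
                     "aspect_ratio": l / w,
                     "steady_iteration": -1 if k is None else k,
                     "status": traj.status})
    return pd.DataFrame(rows)
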