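"""Per-iteration huddle dynamics: perturb, pick the mover, relocate.

One iteration of the model:

1. recompute the boundary polygon and the exterior SC map (warm started);
2. look up the cached canonical temperature field and its boundary flux;
3. integrate the flux over each boundary penguin's preimage arc (q_i);
4. optionally add noise, q_eff_i = q_i + eps * Qbar * eta_i with eta_i
   uniform on (-0.5, 0.5), redrawn every iteration;
5. the *mover* is the boundary penguin with the highest effective loss
   whose removal keeps the huddle valid;
6. the mover re-attaches at the empty site adjacent to the two chosen
   neighbours: the boundary penguin with the least effective loss and, of
   its boundary neighbours, again the least-loss one -- so the destination
   has at least two neighbours and the huddle stays a polygon.

Exactly one penguin changes site per iteration; N is conserved.  With
eps = 0 the dynamics are fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import conformal, lattice, thermal
from .lattice import Huddle, Site


class StuckStateError(Exception):
    """No valid mover or destination exists; the simulation halts."""


@dataclass
class SimConfig:
    """Run configuration (all fields serializable).

    n           number of penguins (>= 5)
    pe          Péclet number (wind strength vs turbulent diffusion)
    r_outer     canonical outer radius where T reaches the ambient value
    eps         noise magnitude relative to the disk-average heat loss
    seed        master seed; initial-huddle and noise streams are spawned
                from it independently
    max_iter    number of relocation iterations
    n_r, n_theta   annulus grid resolution
    record_every   snapshot recording stride
    qbar_mode   'boundary' (default) or 'all': averaging convention for Qbar
    neighbor_rule  'effective' (default) or 'raw': whether destination
                neighbours minimise q_eff or the unperturbed q
    """

    n: int
    pe: float
    r_outer: float = thermal.DEFAULT_R
    eps: float = 0.0
    seed: int = 0
    max_iter: int = 100
    n_r: int = thermal.DEFAULT_NR
    n_theta: int = thermal.DEFAULT_NTHETA
    record_every: int = 1
    qbar_mode: str = "boundary"
    neighbor_rule: str = "effective"
    capacity_correction: bool = False

    def __post_init__(self):
        if self.n < 5:
            raise ValueError("n must be >= 5")
        if self.pe < 0:
            raise ValueError("pe must be nonnegative")
        if self.r_outer <= 1:
            raise ValueError("r_outer must exceed 1")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if self.max_iter < 0 or self.record_every < 1:
            raise ValueError("max_iter must be >= 0, record_every >= 1")
        if self.n_r < 3 or self.n_theta < 8:
            raise ValueError("grid too coarse")
        if self.qbar_mode not in ("boundary", "all"):
            raise ValueError("qbar_mode must be 'boundary' or 'all'")
        if self.neighbor_rule not in ("effective", "raw"):
            raise ValueError("neighbor_rule must be 'effective' or 'raw'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class MoveRecord:
    iteration: int
    penguin: int
    src: Site
    dst: Site


@dataclass
class Trajectory:
    """Recorded history of a simulation run."""

    config: SimConfig
    qbar: float
    initial_sites: tuple
    snapshots: dict = field(default_factory=dict)   # iteration -> site tuple
    movers: list = field(default_factory=list)      # list[MoveRecord]
    widths: np.ndarray = None
    lengths: np.ndarray = None
    centroid_x: np.ndarray = None
    centroid_y: np.ndarray = None
    map_residuals: np.ndarray = None
    fallbacks: np.ndarray = None
    status: str = "completed"
    n_iterations: int = 0

    def mover_ids(self) -> np.ndarray:
        return np.array([m.penguin for m in self.movers], dtype=int)

    def final_huddle(self) -> Huddle:
        if self.n_iterations in self.snapshots:
            return Huddle(self.snapshots[self.n_iterations])
        last = max(self.snapshots) if self.snapshots else 0
        return Huddle(self.snapshots.get(last, self.initial_sites))


# ---------------------------------------------------------------------------
# the individual pipeline stages
# ---------------------------------------------------------------------------

def perturb_heat_loss(profile: thermal.HeatLossProfile, eps: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Effective losses q_i + eps * Qbar * eta_i, eta_i ~ U(-0.5, 0.5)."""
    if eps == 0.0:
        return profile.q.copy()
    if profile.qbar is None:
        raise ValueError("profile has no Qbar; compute disk_reference_loss")
    eta = rng.uniform(-0.5, 0.5, size=len(profile.q))
    return profile.q + eps * profile.qbar * eta


def select_mover(q_eff: np.ndarray, huddle: Huddle,
                 traversal: lattice.BoundaryTraversal) -> int:
    """Index (into the traversal) of the valid mover with maximal loss.

    Candidates whose removal would disconnect the huddle, strand a
    neighbour below two contacts, or pinch the polygon are skipped in
    decreasing order of effective loss.  Ties break on the lower traversal
    index.
    """
    order = np.argsort(-q_eff, kind="stable")
    for idx in order:
        if lattice.validate_removal(huddle, traversal.order[idx]):
            return int(idx)
    raise StuckStateError("no boundary penguin can be removed")


def select_destination(huddle_wo: Huddle,
                       traversal: lattice.BoundaryTraversal,
                       q_eff: np.ndarray, mover_idx: int,
                       mover_site: Site):
    """Destination site for the mover, with a deterministic fallback.

    First neighbour: remaining boundary penguin with the least effective
    loss; second neighbour: least-loss boundary penguin lattice-adjacent to
    the first.  The destination is the empty site adjacent to both.  If it
    is occupied or would break an invariant, the next second neighbour is
    tried, then the next first neighbour.  The vacated site is only used
    when no other option exists.

    Returns (destination, n_fallbacks, identity_move).
    """
    n = traversal.n
    asc = [int(i) for i in np.argsort(q_eff, kind="stable")
           if i != mover_idx]
    sites = traversal.order
    fallbacks = 0
    for fi in asc:
        first = sites[fi]
        first_nbrs = set(lattice.neighbors(first))
        seconds = [sj for sj in asc
                   if sj != fi and sites[sj] in first_nbrs]
        for sj in seconds:
            second = sites[sj]
            shared = [c for c in lattice.neighbors(first)
                      if c in set(lattice.neighbors(second))
                      and c not in huddle_wo.sites]
            for dest in sorted(shared):
                if dest == mover_site:
                    continue
                if lattice.addition_valid(huddle_wo, dest):
                    return dest, fallbacks, False
                fallbacks += 1
            else:
                fallbacks += 1
    # last resort: re-occupy the vacated site (identity move)
    if lattice.addition_valid(huddle_wo, mover_site):
        return mover_site, fallbacks, True
    raise StuckStateError("no eligible destination for the mover")


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

class Simulation:
    """Stateful driver bundling the warm-started map and penguin identities."""

    def __init__(self, config: SimConfig, huddle: Huddle | None = None):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_ss, noise_ss = ss.spawn(2)
        self.rng = np.random.default_rng(noise_ss)
        if huddle is None:
            huddle = lattice.generate_initial_huddle(
                config.n, np.random.default_rng(init_ss))
        elif huddle.N != config.n:
            raise ValueError(
                f"initial huddle has {huddle.N} penguins, config says "
                f"{config.n}")
        self.huddle = huddle
        # penguin identities: stable across relocations
        self.occupant = {s: i for i, s in enumerate(sorted(huddle.sites))}
        self.qbar = thermal.disk_reference_loss(
            config.n, config.pe, config.r_outer, config.n_r, config.n_theta,
            mode=config.qbar_mode)
        self.emap = None
        self.iteration = 0

    def flux(self):
        grid = thermal.solve_temperature(
            self.emap, self.config.pe, self.config.r_outer,
            self.config.n_r, self.config.n_theta,
            capacity_correction=self.config.capacity_correction)
        return thermal.boundary_flux(grid), grid.dtheta

    def step(self):
        """Advance one iteration; returns the MoveRecord."""
        cfg = self.config
        trav = lattice.boundary_traversal(self.huddle)
        poly = conformal.scale_polygon(trav, cfg.n)
        self.emap = conformal.solve_parameter_problem(
            poly, warm_start=self.emap)
        flux, dtheta = self.flux()
        m_angles = thermal.midpoint_preimages(self.emap, poly)
        profile = thermal.heat_loss_per_penguin(
            flux, m_angles, dtheta, qbar=self.qbar)
        q_eff = perturb_heat_loss(profile, cfg.eps, self.rng)
        sel = q_eff if cfg.neighbor_rule == "effective" else profile.q

        mover_idx = select_mover(q_eff, self.huddle, trav)
        mover_site = trav.order[mover_idx]
        huddle_wo = self.huddle.without_site(mover_site)
        dest, n_fb, identity = select_destination(
            huddle_wo, trav, sel, mover_idx, mover_site)
        if identity and cfg.eps == 0.0:
            raise StuckStateError(
                "deterministic identity move: huddle is frozen")
        new_huddle = huddle_wo.with_site(dest)

        pid = self.occupant.pop(mover_site)
        self.occupant[dest] = pid
        self.huddle = new_huddle
        self.iteration += 1
        rec = MoveRecord(self.iteration, pid, mover_site, dest)
        self._last_profile = profile
        self._last_fallbacks = n_fb
        return rec


def step(huddle: Huddle, config: SimConfig,
         rng: np.random.Generator | None = None,
         warm_start=None) -> Huddle:
    """One-shot single iteration (functional form of Simulation.step)."""
    sim = Simulation(config, huddle=huddle)
    if rng is not None:
        sim.rng = rng
    sim.emap = warm_start
    sim.step()
    return sim.huddle


def run_simulation(config: SimConfig,
                   initial_huddle: Huddle | None = None,
                   keep_profiles: bool = False) -> Trajectory:
    """Generate (or accept) an initial huddle and iterate the dynamics."""
    from .diagnostics import shape_metrics  # local import to avoid a cycle

    sim = Simulation(config, huddle=initial_huddle)
    traj = Trajectory(config=config, qbar=sim.qbar,
                      initial_sites=tuple(sorted(sim.huddle.sites)))
    traj.snapshots[0] = traj.initial_sites
    widths, lengths, cx, cy, res, fbs = [], [], [], [], [], []
    profiles = [] if keep_profiles else None
    status = "completed"
    for it in range(1, config.max_iter + 1):
        try:
            rec = sim.step()
        except StuckStateError:
            status = "stuck"
            break
        traj.movers.append(rec)
        sm = shape_metrics(sim.huddle)
        widths.append(sm.width)
        lengths.append(sm.length)
        cx.append(sm.centroid[0])
        cy.append(sm.centroid[1])
        res.append(sim.emap.residual)
        fbs.append(sim._last_fallbacks)
        if profiles is not None:
            profiles.append(sim._last_profile)
        if it % config.record_every == 0 or it == config.max_iter:
            traj.snapshots[it] = tuple(sorted(sim.huddle.sites))
    traj.widths = np.array(widths)
    traj.lengths = np.array(lengths)
    traj.centroid_x = np.array(cx)
    traj.centroid_y = np.array(cy)
    traj.map_residuals = np.array(res)
    traj.fallbacks = np.array(fbs, dtype=int)
    traj.status = status
    traj.n_iterations = len(traj.movers)
    if profiles is not None:
        traj.profiles = profiles
    return traj
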