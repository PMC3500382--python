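"""Configuration files, trajectory serialization, manifests, rendering."""

from __future__ import annotations

import dataclasses
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, conformal, thermal
from .dynamics import MoveRecord, SimConfig, Trajectory
from .lattice import Huddle, boundary_traversal, cartesian_xy


class ConfigError(Exception):
    pass


def load_config(path) -> SimConfig:
    """Read a TOML or JSON run configuration, validating keys and ranges."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)
    except (tomllib.TOMLDecodeError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse ({exc})") from exc
    try:
        return SimConfig.from_dict(raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunManifest:
    """Reproducibility record attached to every saved trajectory."""

    config: dict
    version: str = __version__
    master_seed: int = 0
    stream_seeds: dict = field(default_factory=dict)
    status: str = "pending"
    timings: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @classmethod
    def for_config(cls, config: SimConfig) -> "RunManifest":
        ss = np.random.SeedSequence(config.seed)
        init_ss, noise_ss = ss.spawn(2)
        return cls(config=config.to_dict(), master_seed=config.seed,
                   stream_seeds={"initial_huddle": list(init_ss.entropy if
                                                        isinstance(init_ss.entropy, tuple)
                                                        else [init_ss.entropy])
                                 + list(init_ss.spawn_key),
                                 "noise": list(noise_ss.spawn_key)},
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory (config, snapshots, mover log, series) as JSON."""
    manifest = RunManifest.for_config(traj.config)
    manifest.status = traj.status
    payload = {
        "manifest": dataclasses.asdict(manifest),
        "qbar": traj.qbar,
        "status": traj.status,
        "n_iterations": traj.n_iterations,
        "initial_sites": [list(s) for s in traj.initial_sites],
        "snapshots": {str(k): [list(s) for s in v]
                      for k, v in traj.snapshots.items()},
        "movers": [[m.iteration, m.penguin, list(m.src), list(m.dst)]
                   for m in traj.movers],
        "widths": np.asarray(traj.widths).tolist(),
        "lengths": np.asarray(traj.lengths).tolist(),
        "centroid_x": np.asarray(traj.centroid_x).tolist(),
        "centroid_y": np.asarray(traj.centroid_y).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_trajectory(path) -> Trajectory:
    with open(path) as fh:
        payload = json.load(fh)
    config = SimConfig.from_dict(payload["manifest"]["config"])
    traj = Trajectory(
        config=config, qbar=payload["qbar"],
        initial_sites=tuple(tuple(s) for s in payload["initial_sites"]))
    traj.snapshots = {int(k): tuple(tuple(s) for s in v)
                      for k, v in payload["snapshots"].items()}
    traj.movers = [MoveRecord(it, pid, tuple(src), tuple(dst))
                   for it, pid, src, dst in payload["movers"]]
    traj.widths = np.array(payload["widths"])
    traj.lengths = np.array(payload["lengths"])
    traj.centroid_x = np.array(payload["centroid_x"])
    traj.centroid_y = np.array(payload["centroid_y"])
    traj.status = payload["status"]
    traj.n_iterations = payload["n_iterations"]
    return traj


def export_temperature_csv(grid: thermal.AnnulusGrid, path) -> None:
    """Canonical temperature field as tidy CSV columns r, theta, T."""
    import pandas as pd
    rr, tt = np.meshgrid(grid.r, grid.theta, indexing="ij")
    pd.DataFrame({"r": rr.ravel(), "theta": tt.ravel(),
                  "T": grid.T.ravel()}).to_csv(path, index=False)


def export_temperature_physical_csv(grid: thermal.AnnulusGrid,
                                    emap: conformal.ExteriorMap,
                                    path, L: float = 1.0,
                                    stride: int = 1) -> None:
    """Temperature pushed through the forward map: CSV columns x, y, T
    (physical coordinates, optionally rescaled by the huddle size L)."""
    import pandas as pd
    r = grid.r[::stride]
    th = grid.theta[::stride]
    Z = emap.forward_polar_grid(r, th) * L
    T = grid.T[::stride, ::stride]
    pd.DataFrame({"x": Z.real.ravel(), "y": Z.imag.ravel(),
                  "T": T.ravel()}).to_csv(path, index=False)


def render_state(huddle: Huddle, grid: thermal.AnnulusGrid | None = None,
                 emap: conformal.ExteriorMap | None = None,
                 path=None, max_field_points: int = 4000):
    """Physical-plane snapshot: penguins, boundary polygon and (optionally)
    the temperature field pushed forward through the conformal map."""
    if path is None or str(path) == "":
        raise ValueError("render_state needs an output path")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    trav = boundary_traversal(huddle)
    poly_sp = conformal.scale_polygon(trav, huddle.N)
    L = poly_sp.L

    if grid is not None and emap is not None:
        rr, tt = np.meshgrid(grid.r, grid.theta, indexing="ij")
        stride = max(1, int(np.sqrt(rr.size / max_field_points)))
        zeta = (rr * np.exp(1j * tt))[::stride, ::stride]
        temp = grid.T[::stride, ::stride]
        z = emap.forward(zeta.ravel()) * L
        sc = ax.scatter(z.real, z.imag, c=temp.ravel(), s=6,
                        cmap="coolwarm_r", vmin=0, vmax=1, rasterized=True)
        fig.colorbar(sc, ax=ax, label="T* (nondimensional)")

    centroid = cartesian_xy(huddle.sites).mean(axis=0)
    verts = poly_sp.vertices * L
    ax.plot(np.append(verts.real, verts.real[0]),
            np.append(verts.imag, verts.imag[0]), "k-", lw=1)
    for (x, y) in cartesian_xy(huddle.sites) - centroid:
        ax.add_patch(plt.Circle((x, y), 0.5, color="black", fill=False,
                                lw=0.5))
    ax.set_aspect("equal")
    ax.set_xlabel("x (penguin diameters, wind along +x)")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
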