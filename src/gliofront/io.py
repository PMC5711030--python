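"""Serialisation of profiles, trajectories and configs.

Trajectories go to HDF5 (dense space-time data) or TSV (long format with
columns t, x, C) for plotting; model/experiment parameters are read from
flat YAML or JSON files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .models import ModelParams
from .solver import DensityProfile, FrontTrajectory, Grid1D

__all__ = [
    "load_params",
    "dump_params",
    "save_trajectory",
    "load_trajectory",
    "trajectory_to_tsv",
    "profile_to_tsv",
    "read_profile_tsv",
]


def load_params(path) -> ModelParams:
    """Model parameters from a flat YAML/JSON file (keys D, rho, K, beta,
    kind). Missing keys fall back to the nondimensional defaults
    D = rho = K = 1."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter keys")
    known = {k: data[k] for k in ("D", "rho", "K", "beta", "kind")
             if k in data}
    return ModelParams(**known)


def dump_params(params: ModelParams, path) -> None:
    data = {"D": params.D, "rho": params.rho, "K": params.K,
            "beta": params.beta, "kind": params.kind}
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(data, indent=2))
    else:
        p.write_text(yaml.safe_dump(data))


def save_trajectory(traj: FrontTrajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("profiles", data=traj.profiles,
                         compression="gzip", compression_opts=4)
        f.create_dataset("active", data=traj.active)
        f.create_dataset("front_pos", data=traj.front_pos)
        f.create_dataset("mass", data=traj.mass)
        g = f.attrs
        g["x0"], g["L"], g["nx"] = traj.grid.x0, traj.grid.L, traj.grid.nx
        g["D"], g["rho"], g["K"] = (traj.params.D, traj.params.rho,
                                    traj.params.K)
        g["beta"], g["kind"] = traj.params.beta, traj.params.kind
        g["front_level"] = traj.front_level
        g["clamped_nodes"] = traj.clamped_nodes
        g["meta"] = json.dumps(traj.meta)


def load_trajectory(path) -> FrontTrajectory:
    with h5py.File(path, "r") as f:
        a = f.attrs
        grid = Grid1D(float(a["x0"]), float(a["L"]), int(a["nx"]))
        params = ModelParams(D=float(a["D"]), rho=float(a["rho"]),
                             K=float(a["K"]), beta=float(a["beta"]),
                             kind=str(a["kind"]))
        return FrontTrajectory(
            grid=grid, params=params, times=f["times"][:],
            profiles=f["profiles"][:], active=f["active"][:].astype(bool),
            front_pos=f["front_pos"][:], mass=f["mass"][:],
            front_level=float(a["front_level"]),
            clamped_nodes=int(a["clamped_nodes"]),
            meta=json.loads(str(a["meta"])))


def trajectory_to_tsv(traj: FrontTrajectory, path,
                      profile_stride: int = 1) -> None:
    """Long-format TSV (t, x, C) of the stored profiles."""
    ks = range(0, len(traj.times), profile_stride)
    frames = [pd.DataFrame({"t": traj.times[k], "x": traj.grid.x,
                            "C": traj.profiles[k]}) for k in ks]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def profile_to_tsv(profile: DensityProfile, path) -> None:
    pd.DataFrame({"t": profile.t, "x": profile.grid.x, "C": profile.C,
                  "active": profile.active.astype(int)}).to_csv(
        path, sep="\t", index=False)


def read_profile_tsv(path) -> DensityProfile:
    """Profile from a TSV with columns x, C [, t, active]; the grid is
    reconstructed from the (uniform) x column."""
    df = pd.read_csv(path, sep="\t")
    if not {"x", "C"}.issubset(df.columns):
        raise ValueError("profile TSV needs columns x and C")
    x = df["x"].to_numpy(dtype=float)
    dxs = np.diff(x)
    if len(x) < 16 or not np.allclose(dxs, dxs[0], rtol=1e-6):
        raise ValueError("x must be uniform with >= 16 nodes")
    dx = float(dxs[0])
    grid = Grid1D(x0=float(x[0]) - dx / 2, L=dx * len(x), nx=len(x))
    t = float(df["t"].iloc[0]) if "t" in df else 0.0
    active = (df["active"].to_numpy().astype(bool)
              if "active" in df else None)
    return DensityProfile(grid, df["C"].to_numpy(dtype=float), t, active)
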