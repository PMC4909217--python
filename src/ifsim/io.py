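"""Configuration files, trajectory/length-table/snapshot I/O.

All on-disk formats are plain text: YAML for run configurations, TSV with
``#`` header lines for trajectories and length tables, per-bead TSV or XYZ
for snapshots, JSON for analysis reports.  Writers embed the full parameter
set and seed so every output is self-describing and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .analysis import LengthDistribution
from .engine import Trajectory
from .polymer import PeriodicBox, SimulationParams, SystemState, init_system

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "read_length_table",
    "write_length_table",
    "write_snapshot",
]


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


_PARAM_KEYS = {
    "bead_diameter",
    "max_bond_angle",
    "reaction_angle",
    "angle_measure",
    "min_reg_angle",
    "beads_per_ulf",
    "ulf_length_nm",
    "ulf_repeat_nm",
    "sweep_time_s",
    "ulf_mass_g",
    "bond_min_frac",
    "bond_max_frac",
    "max_displacement_frac",
}
_BOX_KEYS = {"edge_nm", "volume_um3", "concentration_gpl"}
_STOP_KEYS = {"target_mean_ulf", "max_sweeps"}
_TOP_KEYS = _PARAM_KEYS | {"n0", "box", "stop", "record_every", "anneal_every", "seed"}


@dataclass
class RunConfig:
    """A fully validated assembly-run definition."""

    params: SimulationParams
    n0: int
    box_spec: dict           # exactly one of edge_nm / volume_um3 / concentration_gpl
    stop: dict               # target_mean_ulf and/or max_sweeps
    record_every: int = 1000
    anneal_every: int = 1
    seed: int = 0

    def make_box(self) -> PeriodicBox:
        if "edge_nm" in self.box_spec:
            return PeriodicBox(float(self.box_spec["edge_nm"]))
        if "volume_um3" in self.box_spec:
            return PeriodicBox.from_volume(float(self.box_spec["volume_um3"]))
        return PeriodicBox.from_concentration(
            self.n0, float(self.box_spec["concentration_gpl"]), self.params
        )

    def make_state(self, seed: Optional[int] = None) -> SystemState:
        return init_system(self.n0, self.make_box(), self.params,
                           seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.pop("seed", None)
        d.update(
            n0=self.n0,
            box=dict(self.box_spec),
            stop=dict(self.stop),
            record_every=self.record_every,
            anneal_every=self.anneal_every,
            seed=self.seed,
        )
        return d


def _config_from_dict(raw: dict) -> RunConfig:
    problems: List[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    box = raw.get("box")
    if not isinstance(box, dict):
        problems.append("missing 'box' section")
        box = {}
    bad_box = set(box) - _BOX_KEYS
    if bad_box:
        problems.append(f"unknown box keys: {sorted(bad_box)}")
    n_spec = len(set(box) & _BOX_KEYS)
    if n_spec != 1:
        problems.append(
            "box must give exactly one of edge_nm, volume_um3, concentration_gpl"
        )
    stop = raw.get("stop")
    if not isinstance(stop, dict) or not (set(stop) & _STOP_KEYS):
        problems.append("stop must give target_mean_ulf and/or max_sweeps")
        stop = {}
    bad_stop = set(stop) - _STOP_KEYS
    if bad_stop:
        problems.append(f"unknown stop keys: {sorted(bad_stop)}")
    n0 = raw.get("n0")
    if not isinstance(n0, int) or n0 < 1:
        problems.append("n0 must be a positive integer")
    for key in ("record_every", "anneal_every"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 1):
            problems.append(f"{key} must be a positive integer")
    for key, val in box.items():
        if key in _BOX_KEYS and (not isinstance(val, (int, float)) or val <= 0):
            problems.append(f"box.{key} must be positive")
    params = None
    if not problems:
        try:
            params = SimulationParams(
                seed=int(raw.get("seed", 0)),
                **{k: raw[k] for k in _PARAM_KEYS if k in raw},
            )
        except (TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(
        params=params,
        n0=int(n0),
        box_spec={k: float(v) for k, v in box.items()},
        stop={k: stop[k] for k in stop},
        record_every=int(raw.get("record_every", 1000)),
        anneal_every=int(raw.get("anneal_every", 1)),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    return _config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """TSV with a ``#``-prefixed header carrying params, n0 and seed."""
    meta = {
        "n0": traj.n0,
        "seed": traj.seed,
        "params": dataclasses.asdict(traj.params),
    }
    with open(path, "w") as fh:
        fh.write(f"# ifsim-trajectory {json.dumps(meta, sort_keys=True)}\n")
        fh.write("sweep\tn_filaments\tmean_ulf\tacceptance\n")
        for s, nf, a in zip(traj.sweeps, traj.n_filaments, traj.acceptance):
            fh.write(f"{int(s)}\t{int(nf)}\t{traj.n0 / nf:.6f}\t{a:.6f}\n")


def read_trajectory(path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; enforces monotonicity."""
    meta = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "ifsim-trajectory" in line:
                    try:
                        meta = json.loads(line.split(None, 2)[2])
                    except (IndexError, json.JSONDecodeError) as exc:
                        raise ValueError(f"{path}:{ln}: bad header: {exc}") from exc
                continue
            if line.startswith("sweep\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    if meta is None:
        raise ValueError(f"{path}: missing ifsim-trajectory header")
    params = SimulationParams(**meta["params"])
    sweeps = np.array([r[0] for r in rows], dtype=np.int64)
    nfil = np.array([r[1] for r in rows], dtype=np.int64)
    acc = np.array([r[2] for r in rows])
    return Trajectory(
        sweeps=sweeps, n_filaments=nfil, acceptance=acc,
        n0=int(meta["n0"]), params=params, seed=int(meta["seed"]),
    )


# --------------------------------------------------------------------------
# length tables and snapshots
# --------------------------------------------------------------------------

def read_length_table(path) -> LengthDistribution:
    """TSV with a required ``length_nm`` column and optional ``time_s`` /
    ``source`` columns; lines starting with ``#`` are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "length_nm" not in df.columns:
        raise ValueError(f"{path}: missing required column 'length_nm'")
    time_label = None
    if "time_s" in df.columns and df["time_s"].notna().any():
        time_label = float(df["time_s"].dropna().iloc[0])
    source = "file"
    if "source" in df.columns and df["source"].notna().any():
        source = str(df["source"].dropna().iloc[0])
    return LengthDistribution(df["length_nm"].to_numpy(dtype=float),
                              time_label=time_label, source=source)


def write_length_table(dist: LengthDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ifsim-lengths source={dist.source}\n")
        fh.write("length_nm\ttime_s\tsource\n")
        t = "" if dist.time_label is None else f"{dist.time_label:g}"
        for L in dist.lengths_nm:
            fh.write(f"{L:.4f}\t{t}\t{dist.source}\n")


def write_snapshot(state: SystemState, path, fmt: str = "tsv") -> None:
    """Per-bead coordinate dump: TSV (filament_id, bead_index, x, y, z) or
    XYZ for molecular viewers.  Coordinates are unwrapped, nm."""
    fils = state.filaments()
    header = {
        "sweep_count": state.sweep_count,
        "n0": state.n0,
        "box_edge_nm": state.box.edge,
        "params": dataclasses.asdict(state.params),
    }
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# ifsim-snapshot {json.dumps(header, sort_keys=True)}\n")
            fh.write("filament_id\tbead_index\tx_nm\ty_nm\tz_nm\n")
            for fid, f in enumerate(fils):
                for b, (x, y, z) in enumerate(f.beads):
                    fh.write(f"{fid}\t{b}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{state.n_beads}\n")
            fh.write(f"ifsim snapshot sweep={state.sweep_count}\n")
            for f in fils:
                for x, y, z in f.beads:
                    fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")
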