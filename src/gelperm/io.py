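"""File formats: extended XYZ snapshots, HDF5 systems/trajectories, YAML
configuration, and run manifests.

Extended-XYZ columns are ``species x y z nx ny nz np_id`` with the box in the
comment line (``Lattice=...`` as in the usual extended-XYZ convention);
species letters are P (polymer), N (node), S (shell/NP bead).  All round
trips are lossless at full double precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .system import BeadSystem, NetworkSpec, NODE, NP_BEAD, POLYMER
from .dynamics import Trajectory

_SPECIES = {POLYMER: "P", NODE: "N", NP_BEAD: "S"}
_SPECIES_INV = {v: k for k, v in _SPECIES.items()}


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz_frame(fh, positions, normals, bead_type, np_membership,
                    box_length: float, time: float = 0.0) -> None:
    n = len(positions)
    fh.write(f"{n}\n")
    fh.write(
        f'Lattice="{box_length:.17g} 0 0 0 {box_length:.17g} 0 0 0 '
        f'{box_length:.17g}" Properties=species:S:1:pos:R:3:normal:R:3:np_id:I:1 '
        f"Time={time:.17g}\n"
    )
    for i in range(n):
        p = positions[i]
        m = normals[i]
        fh.write(
            f"{_SPECIES[int(bead_type[i])]} "
            f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
            f"{m[0]:.17g} {m[1]:.17g} {m[2]:.17g} {int(np_membership[i])}\n"
        )


def write_xyz(path, system: BeadSystem, time: float = 0.0) -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, system.positions, system.normals, system.bead_type,
                        system.np_membership, system.box_length, time)


def write_xyz_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            write_xyz_frame(fh, traj.wrapped_positions[f], traj.normals[f],
                            traj.bead_type, traj.np_membership,
                            traj.box_length, float(traj.times[f]))


class XYZParseError(ValueError):
    pass


def read_xyz(path):
    """Read all frames of an extended-XYZ file.

    Returns a list of dicts with keys positions, normals, bead_type, np_id,
    box_length, time.  Malformed or truncated input raises
    :class:`XYZParseError` naming the offending frame and line.
    """
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    frame_no = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        frame_no += 1
        try:
            n = int(lines[ln].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame_no}, line {ln + 1}: expected atom count") from exc
        if ln + 2 + n > len(lines):
            raise XYZParseError(
                f"frame {frame_no} truncated: expected {n} atom lines "
                f"after line {ln + 2}, file ends at line {len(lines)}")
        comment = lines[ln + 1]
        box = _parse_lattice(comment, frame_no, ln + 2)
        time = 0.0
        for tok in comment.split():
            if tok.startswith("Time="):
                time = float(tok[5:])
        pos = np.empty((n, 3))
        nrm = np.empty((n, 3))
        btype = np.empty(n, dtype=np.int8)
        np_id = np.empty(n, dtype=np.int32)
        for i in range(n):
            row = lines[ln + 2 + i].split()
            if len(row) != 8:
                raise XYZParseError(
                    f"frame {frame_no}, line {ln + 3 + i}: expected 8 columns, "
                    f"got {len(row)}")
            btype[i] = _SPECIES_INV.get(row[0], POLYMER)
            pos[i] = [float(x) for x in row[1:4]]
            nrm[i] = [float(x) for x in row[4:7]]
            np_id[i] = int(row[7])
        frames.append(dict(positions=pos, normals=nrm, bead_type=btype,
                           np_id=np_id, box_length=box, time=time))
        ln += 2 + n
    return frames


def _parse_lattice(comment: str, frame_no: int, line: int) -> float:
    if 'Lattice="' not in comment:
        raise XYZParseError(f"frame {frame_no}, line {line}: missing Lattice")
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    return float(lat[0])


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def save_system_h5(group: h5py.Group, system: BeadSystem) -> None:
    for name in ("positions", "velocities", "normals", "bead_type",
                 "np_membership", "bond_i", "bond_j", "bond_k", "bond_r0",
                 "tether_idx", "tether_anchor", "tether_k", "masses",
                 "np_rigid", "np_start", "np_count"):
        group.create_dataset(name, data=getattr(system, name))
    group.attrs["box_length"] = system.box_length
    group.attrs["n_chains"] = system.n_chains
    group.attrs["np_class"] = json.dumps(system.np_class)
    for i, b in enumerate(system.body_positions):
        group.create_dataset(f"body_positions/{i}", data=b)
        group.create_dataset(f"body_normals/{i}", data=system.body_normals[i])


def load_system_h5(group: h5py.Group) -> BeadSystem:
    kw = {name: group[name][...] for name in
          ("positions", "velocities", "normals", "bead_type", "np_membership",
           "bond_i", "bond_j", "bond_k", "bond_r0", "tether_idx",
           "tether_anchor", "tether_k", "masses", "np_rigid", "np_start",
           "np_count")}
    n_np = len(kw["np_start"])
    body_p = [group[f"body_positions/{i}"][...] for i in range(n_np)
              ] if "body_positions" in group else []
    body_n = [group[f"body_normals/{i}"][...] for i in range(n_np)
              ] if "body_normals" in group else []
    return BeadSystem(
        box_length=float(group.attrs["box_length"]),
        n_chains=int(group.attrs["n_chains"]),
        np_class=json.loads(group.attrs["np_class"]),
        body_positions=body_p, body_normals=body_n,
        np_rigid=kw.pop("np_rigid").astype(bool), **kw)


def save_trajectory_h5(path, traj: Trajectory, system: BeadSystem | None = None
                       ) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trajectory")
        for name in ("times", "wrapped_positions", "unwrapped_positions",
                     "normals", "centroid_times", "np_centroids_unwrapped",
                     "energies", "kinetic_energies", "bead_type",
                     "np_membership"):
            g.create_dataset(name, data=getattr(traj, name))
        g.attrs["box_length"] = traj.box_length
        g.attrs["np_class"] = json.dumps(traj.np_class)
        if system is not None:
            save_system_h5(f.create_group("system"), system)


def load_trajectory_h5(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        g = f["trajectory"]
        kw = {name: g[name][...] for name in
              ("times", "wrapped_positions", "unwrapped_positions", "normals",
               "centroid_times", "np_centroids_unwrapped", "energies",
               "kinetic_energies", "bead_type", "np_membership")}
        return Trajectory(box_length=float(g.attrs["box_length"]),
                          np_class=json.loads(g.attrs["np_class"]), **kw)


# ---------------------------------------------------------------------------
# config and manifests
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_config_yaml(path, config) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config) -> str:
    """Hash of the scientific configuration (output paths excluded)."""
    plain = _to_plain(config)
    if isinstance(plain, dict):
        plain.pop("output_dir", None)
    return hashlib.sha256(
        json.dumps(plain, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, config, seeds, extra: dict | None = None) -> None:
    """Run manifest: config hash, seeds and versions, enough to reproduce."""
    import numba
    import scipy

    manifest = {
        "config": _to_plain(config),
        "config_hash": config_hash(config),
        "seeds": [int(s) for s in seeds],
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "numba": numba.__version__},
    }
    if extra:
        manifest.update(_to_plain(extra))
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
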