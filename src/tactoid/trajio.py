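"""Trajectory and topology readers/writers plus run manifests.

Formats:

* XYZ - human-readable frames (species label + nm coordinates, box and time
  in the comment line); lossy (no charges/topology).
* GRO-style - single-configuration coordinate file in nm with species-coded
  residue names and the cubic box vector.
* HDF5 container - lossless round-trip of a :class:`Trajectory` including
  charges, diameters, bonded topology and the energy log.

Conventions: all file positions in nm; particle indices are 0-based in the
binary container and 1-based in the human-readable formats (each header
says so).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .state import SPECIES_LABELS, SystemState
from .trajectory import Trajectory

_XYZ_NAMES = {0: "NPS", 1: "PEB", 2: "CAT", 3: "ANI"}
_CODE_OF = {v: k for k, v in _XYZ_NAMES.items()}


# ---------------------------------------------------------------- XYZ

def write_xyz(traj: Trajectory, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{traj.n_particles}\n")
            fh.write(f"box_nm={traj.box_length:.6f} time_ps={t:.6f} units=nm 1-based\n")
            for code, (x, y, z) in zip(traj.species, frame):
                fh.write(f"{_XYZ_NAMES[int(code)]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: Union[str, Path]) -> Trajectory:
    """Read XYZ frames back (coordinates, species and box only)."""
    frames, times, species = [], [], None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        header = dict(kv.split("=") for kv in lines[i + 1].split() if "=" in kv)
        box = float(header.get("box_nm", 0.0))
        times.append(float(header.get("time_ps", 0.0)))
        rows = lines[i + 2 : i + 2 + n]
        sp = np.array([_CODE_OF[r.split()[0]] for r in rows])
        coords = np.array([[float(v) for v in r.split()[1:4]] for r in rows])
        frames.append(coords)
        species = sp
        i += 2 + n
    frames = np.stack(frames)
    n = frames.shape[1]
    return Trajectory(
        frames=frames,
        times=np.array(times),
        box_length=box,
        species=species,
        charges=np.zeros(n),
        diameters=np.zeros(n),
        molecule=np.zeros(n, dtype=np.int64),
        metadata={"source": str(path), "format": "xyz"},
    )


# ---------------------------------------------------------------- GRO

def write_gro(state: SystemState, path: Union[str, Path], title: str = "tactoid") -> None:
    """GRO-style coordinate file (nm, 1-based atom numbering)."""
    pos = state.wrapped_positions()
    with open(path, "w") as fh:
        fh.write(f"{title}; positions nm; 1-based indices\n")
        fh.write(f"{state.n_particles}\n")
        for i, (code, mol, (x, y, z)) in enumerate(
            zip(state.species, state.molecule, pos), start=1
        ):
            name = _XYZ_NAMES[int(code)]
            fh.write(f"{int(mol) % 100000:5d}{name:<5s}{name:>5s}{i % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{state.box_length:10.5f}{state.box_length:10.5f}{state.box_length:10.5f}\n")


def read_gro(path: Union[str, Path]) -> SystemState:
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    species, molecule, coords = [], [], []
    for line in lines[2 : 2 + n]:
        molecule.append(int(line[0:5]))
        species.append(_CODE_OF[line[5:10].strip()])
        coords.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
    box = float(lines[2 + n].split()[0])
    return SystemState(
        positions=np.array(coords),
        charges=np.zeros(n),
        diameters=np.zeros(n),
        species=np.array(species),
        molecule=np.array(molecule),
        box_length=box,
        metadata={"source": str(path), "format": "gro"},
    )


# ---------------------------------------------------------------- HDF5

def write_h5(traj: Trajectory, path: Union[str, Path]) -> None:
    """Lossless trajectory container (0-based indices)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=traj.frames)
        f.create_dataset("times", data=traj.times)
        for name in ("species", "charges", "diameters", "molecule"):
            f.create_dataset(name, data=getattr(traj, name))
        f.attrs["box_length"] = traj.box_length
        f.attrs["indexing"] = "0-based"
        f.attrs["units"] = "nm, ps, kBT"
        for key in ("seed", "method"):
            if key in traj.metadata and traj.metadata[key] is not None:
                f.attrs[key] = traj.metadata[key]
        if traj.energies is not None:
            grp = f.create_group("energies")
            for col in traj.energies.columns:
                grp.create_dataset(col, data=traj.energies[col].to_numpy())
        final = traj.metadata.get("final_state")
        if final is not None and final.velocities is not None:
            # restart data: exact final phase-space point of the run
            f.create_dataset("final_positions", data=final.positions)
            f.create_dataset("final_velocities", data=final.velocities)


def read_h5(path: Union[str, Path]) -> Trajectory:
    with h5py.File(path, "r") as f:
        energies = None
        if "energies" in f:
            energies = pd.DataFrame({k: f["energies"][k][...] for k in f["energies"]})
        meta = {k: f.attrs[k] for k in f.attrs if k not in ("box_length",)}
        meta["source"] = str(path)
        if "final_positions" in f:
            meta["final_positions"] = f["final_positions"][...]
            meta["final_velocities"] = f["final_velocities"][...]
        return Trajectory(
            frames=f["frames"][...],
            times=f["times"][...],
            box_length=float(f.attrs["box_length"]),
            species=f["species"][...],
            charges=f["charges"][...],
            diameters=f["diameters"][...],
            molecule=f["molecule"][...],
            energies=energies,
            metadata=meta,
        )


def write_frames(traj: Trajectory, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Dispatch on format (xyz, gro_style, binary_container) or file suffix."""
    fmt = format or {".xyz": "xyz", ".gro": "gro_style", ".h5": "binary_container"}.get(
        Path(path).suffix, None
    )
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "gro_style":
        write_gro(traj.state_at(traj.n_frames - 1), path)
    elif fmt == "binary_container":
        write_h5(traj, path)
    else:
        raise ValueError(f"cannot infer format for {path}")


def read_frames(path: Union[str, Path], format: Optional[str] = None) -> Trajectory:
    fmt = format or {".xyz": "xyz", ".h5": "binary_container"}.get(Path(path).suffix, None)
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "binary_container":
        return read_h5(path)
    raise ValueError(f"cannot infer format for {path}")


# ---------------------------------------------------------------- topology listing

def write_topology_listing(state: SystemState, path: Union[str, Path]) -> None:
    """Plain-text charge/bond/angle listing (1-based indices)."""
    with open(path, "w") as fh:
        fh.write("# tactoid topology listing; 1-based particle indices; nm, e, kBT units\n")
        fh.write(f"# particles {state.n_particles}  box_nm {state.box_length}\n")
        fh.write("[particles]  # index species molecule charge_e diameter_nm\n")
        for i in range(state.n_particles):
            fh.write(
                f"{i + 1} {SPECIES_LABELS[int(state.species[i])]} "
                f"{int(state.molecule[i]) + 1} {state.charges[i]:g} {state.diameters[i]:g}\n"
            )
        fh.write("[bonds]  # i j r0_nm k_kBT_nm2\n")
        for (i, j), r0, k in zip(state.bonds, state.bond_r0, state.bond_k):
            fh.write(f"{i + 1} {j + 1} {r0:g} {k:g}\n")
        fh.write("[angles]  # i j k theta0=pi k_kBT_rad2\n")
        for (i, j, k), ka in zip(state.angles, state.angle_k):
            fh.write(f"{i + 1} {j + 1} {k + 1} {ka:g}\n")


# ---------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    """Provenance record: config snapshot, seeds, digests, timings."""

    config: dict
    seed: int
    code_version: str = ""
    inputs: dict = field(default_factory=dict)  # name -> sha256
    outputs: dict = field(default_factory=dict)
    n_steps: int = 0
    wall_time_s: float = 0.0
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def register_file(self, kind: str, path: Union[str, Path]) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        target = self.inputs if kind == "input" else self.outputs
        target[str(path)] = digest

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
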