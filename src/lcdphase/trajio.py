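"""Trajectory input/output: extended XYZ, PDB topology + DCD frames, npz.

Extended XYZ is the plain-text interchange format (one bead per residue with
chain ids in an extra column); PDB/DCD go through mdtraj for use with
standard visualization tools.  ``save_npz``/``load_npz`` are the compact
internal round-trip used by the pipeline for resumable runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .system import SystemConfiguration, Trajectory

__all__ = [
    "save_xyz", "load_xyz", "save_npz", "load_npz",
    "write_pdb", "write_dcd",
]


def save_xyz(traj: Trajectory, path: str | Path) -> None:
    """Extended XYZ: per-frame Lattice and Time in the comment line, columns
    ``code chain x y z``."""
    path = Path(path)
    chain_of = np.empty(traj.n_beads, dtype=int)
    for c, (start, end) in enumerate(traj.chains):
        chain_of[start:end] = c
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            bx, by, bz = traj.boxes[f]
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f'Lattice="{bx} 0 0 0 {by} 0 0 0 {bz}" '
                f"Time={traj.times[f]} "
                'Properties=species:S:1:chain:I:1:pos:R:3\n'
            )
            for i in range(traj.n_beads):
                x, y, z = traj.frames[f][i]
                fh.write(
                    f"{traj.bead_codes[i]} {chain_of[i]} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def load_xyz(path: str | Path) -> Trajectory:
    path = Path(path)
    frames, boxes, times = [], [], []
    codes: list[str] = []
    chain_ids: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    first = True
    while k < len(lines):
        n = int(lines[k].strip())
        comment = lines[k + 1]
        lattice = comment.split('Lattice="')[1].split('"')[0].split()
        boxes.append([float(lattice[0]), float(lattice[4]), float(lattice[8])])
        time = 0.0
        for tok in comment.split():
            if tok.startswith("Time="):
                time = float(tok[5:])
        times.append(time)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if first:
                codes.append(parts[0])
                chain_ids.append(int(parts[1]))
            pos[i] = [float(parts[2]), float(parts[3]), float(parts[4])]
        frames.append(pos)
        first = False
        k += 2 + n
    chains = []
    start = 0
    for i in range(1, len(chain_ids) + 1):
        if i == len(chain_ids) or chain_ids[i] != chain_ids[start]:
            chains.append((start, i))
            start = i
    return Trajectory(
        frames=np.asarray(frames), boxes=np.asarray(boxes),
        times=np.asarray(times), chains=chains, bead_codes=codes,
    )


def save_npz(traj: Trajectory, path: str | Path) -> None:
    np.savez_compressed(
        path,
        frames=traj.frames,
        boxes=traj.boxes,
        times=traj.times,
        chains=np.asarray(traj.chains, dtype=np.int64),
        bead_codes=np.asarray(traj.bead_codes),
        provenance=json.dumps(traj.provenance, default=str),
    )


def load_npz(path: str | Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        return Trajectory(
            frames=data["frames"],
            boxes=data["boxes"],
            times=data["times"],
            chains=[tuple(c) for c in data["chains"]],
            bead_codes=[str(c) for c in data["bead_codes"]],
            provenance=json.loads(str(data["provenance"])),
        )


def _mdtraj_topology(traj: Trajectory):
    import mdtraj

    top = mdtraj.Topology()
    for start, end in traj.chains:
        chain = top.add_chain()
        prev = None
        for i in range(start, end):
            code = traj.bead_codes[i]
            name = "SEP" if code == "s" else code
            res = top.add_residue(name, chain)
            atom = top.add_atom("CA", mdtraj.core.element.carbon, res)
            if prev is not None:
                top.add_bond(prev, atom)
            prev = atom
    return top


def write_pdb(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """One-bead-per-residue PDB topology of a single frame (Angstrom)."""
    import mdtraj

    top = _mdtraj_topology(traj)
    t = mdtraj.Trajectory(
        xyz=traj.frames[frame : frame + 1] / 10.0,  # mdtraj uses nm
        topology=top,
        unitcell_lengths=traj.boxes[frame : frame + 1] / 10.0,
        unitcell_angles=np.full((1, 3), 90.0),
    )
    t.save_pdb(str(path))


def write_dcd(traj: Trajectory, path: str | Path) -> None:
    import mdtraj

    top = _mdtraj_topology(traj)
    t = mdtraj.Trajectory(
        xyz=traj.frames / 10.0,
        topology=top,
        time=traj.times,
        unitcell_lengths=traj.boxes / 10.0,
        unitcell_angles=np.full((traj.n_frames, 3), 90.0),
    )
    t.save_dcd(str(path))
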