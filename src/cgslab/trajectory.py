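"""Trajectory container and extended-XYZ I/O.

The on-disk default is a human-readable extended XYZ: per frame a bead count
line, a comment line carrying the time (ps), the orthorhombic box and (first
frame only) a JSON metadata blob, then one line per bead with bead type,
position, molecule id, 1-based chain index and species label.  Positions are
stored to fixed precision; reading a written file reproduces them exactly at
that precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class TrajectoryFormatError(ValueError):
    """Truncated or inconsistent trajectory file."""


@dataclass
class Trajectory:
    """Time-ordered bead positions plus per-bead metadata.

    ``positions`` has shape (n_frames, n_beads, 3) in Angstrom, ``times`` is
    strictly increasing in ps, ``box`` is the (Lx, Ly, Lz) periodic box.
    Per-bead arrays (types, mol_id, species, chain_index, mass, sigma,
    charge) are copied from the generating topology; ``metadata`` carries
    arbitrary JSON-serializable ground truth (used by synthetic generators).
    """

    positions: np.ndarray
    times: np.ndarray
    box: np.ndarray
    types: np.ndarray
    mol_id: np.ndarray
    species: np.ndarray
    chain_index: np.ndarray
    mass: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    metadata: dict = field(default_factory=dict)
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (frames, beads, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def species_names(self):
        return sorted(set(self.species.tolist()))

    @classmethod
    def from_topology(cls, topology, positions, times, metadata=None,
                      velocities=None) -> "Trajectory":
        return cls(
            positions=np.asarray(positions, dtype=float),
            times=np.asarray(times, dtype=float),
            box=np.asarray(topology.box, dtype=float),
            types=topology.types,
            mol_id=topology.mol_id,
            species=topology.species,
            chain_index=topology.chain_index,
            mass=topology.mass,
            sigma=topology.sigma,
            charge=topology.charge,
            metadata=metadata or {},
            velocities=velocities,
        )


def write_trajectory(traj: Trajectory, target) -> None:
    """Write a trajectory as extended XYZ (path or text stream)."""
    if isinstance(target, (str, Path)):
        with open(target, "w") as fh:
            write_trajectory(traj, fh)
        return
    box = traj.box
    for f in range(max(traj.n_frames, 1)):
        empty = traj.n_frames == 0
        n = 0 if empty else traj.n_beads
        target.write(f"{n}\n")
        comment = (
            f'Time={0.0 if empty else traj.times[f]:.6f} '
            f'Lattice="{box[0]:.6f} 0 0 0 {box[1]:.6f} 0 0 0 {box[2]:.6f}"'
        )
        if f == 0 and traj.metadata:
            comment += " Metadata=" + json.dumps(traj.metadata, sort_keys=True)
        target.write(comment + "\n")
        if empty:
            break
        for b in range(n):
            x, y, z = traj.positions[f, b]
            target.write(
                f"{traj.types[b]} {x:.8f} {y:.8f} {z:.8f} "
                f"{int(traj.mol_id[b])} {int(traj.chain_index[b])} "
                f"{traj.species[b]}\n"
            )


def read_trajectory(source) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    Bead parameters (mass, sigma, charge) are resolved from the default
    parameter table by bead type.  Raises TrajectoryFormatError on truncation
    or frame-to-frame bead-count mismatch, naming the frame.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_trajectory(fh)
    lines = source.read().splitlines()
    frames, times = [], []
    types = mol_id = species = chain_index = None
    metadata: dict = {}
    box = None
    pos_frames = []
    li = 0
    frame = 0
    while li < len(lines):
        if not lines[li].strip():
            li += 1
            continue
        try:
            n = int(lines[li].strip())
        except ValueError as err:
            raise TrajectoryFormatError(
                f"frame {frame}: bad bead-count line {li + 1}"
            ) from err
        if li + 1 >= len(lines):
            raise TrajectoryFormatError(f"frame {frame}: missing comment line")
        comment = lines[li + 1]
        time, box_f, meta = _parse_comment(comment, frame)
        if box is None:
            box = box_f
        if meta:
            metadata = meta
        body = lines[li + 2: li + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(
                f"frame {frame}: truncated (expected {n} beads, got {len(body)})"
            )
        if frames and n != len(frames[0]):
            raise TrajectoryFormatError(
                f"frame {frame}: bead count {n} != {len(frames[0])}"
            )
        pos = np.zeros((n, 3))
        t_, m_, c_, s_ = [], [], [], []
        for b, line in enumerate(body):
            parts = line.split()
            if len(parts) < 7:
                raise TrajectoryFormatError(
                    f"frame {frame}: malformed bead line {li + 3 + b}"
                )
            t_.append(parts[0])
            pos[b] = [float(parts[1]), float(parts[2]), float(parts[3])]
            m_.append(int(parts[4]))
            c_.append(int(parts[5]))
            s_.append(parts[6])
        if types is None:
            types = np.array(t_, dtype=object)
            mol_id = np.array(m_, dtype=np.int64)
            chain_index = np.array(c_, dtype=np.int64)
            species = np.array(s_, dtype=object)
        if n > 0:
            frames.append(pos)
            times.append(time)
            pos_frames.append(pos)
        li += 2 + n
        frame += 1
    if box is None:
        raise TrajectoryFormatError("no frames found")
    if types is None:
        types = np.empty(0, dtype=object)
        mol_id = chain_index = np.empty(0, dtype=np.int64)
        species = np.empty(0, dtype=object)
    from cgslab.params import default_table

    n_beads = len(types)
    if n_beads:
        arrs = default_table().arrays_for(types.tolist())
        mass, sigma, charge = arrs["mass"], arrs["sigma"], arrs["lambda"] * 0
        charge = arrs["charge"]
    else:
        mass = sigma = charge = np.empty(0)
    positions = (
        np.asarray(pos_frames) if pos_frames else np.empty((0, n_beads, 3))
    )
    return Trajectory(
        positions=positions,
        times=np.asarray(times, dtype=float),
        box=box,
        types=types,
        mol_id=mol_id,
        species=species,
        chain_index=chain_index,
        mass=mass,
        sigma=sigma,
        charge=charge,
        metadata=metadata,
    )


def _parse_comment(comment: str, frame: int):
    time = 0.0
    box = None
    meta = {}
    if "Time=" in comment:
        time = float(comment.split("Time=")[1].split()[0])
    if 'Lattice="' in comment:
        lat = comment.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
    else:
        raise TrajectoryFormatError(f"frame {frame}: comment line lacks Lattice")
    if "Metadata=" in comment:
        meta = json.loads(comment.split("Metadata=", 1)[1])
    return time, box, meta


def to_dcd(traj: Trajectory, path) -> None:
    """Optional binary DCD export for interoperability with MD viewers."""
    import MDAnalysis as mda

    u = mda.Universe.empty(
        traj.n_beads, trajectory=True, n_residues=traj.n_beads,
        atom_resindex=np.arange(traj.n_beads),
    )
    with mda.Writer(str(path), traj.n_beads) as writer:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f]
            u.dimensions = [traj.box[0], traj.box[1], traj.box[2], 90, 90, 90]
            writer.write(u.atoms)
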