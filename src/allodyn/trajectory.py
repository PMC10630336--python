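"""Trajectory container and I/O.

Coordinates are frames × atoms × 3 in Å, times in ps.  DCD and XTC files are
read through mdtraj (coordinates converted from nm); in addition a portable
plain-text format (extension ``.trjtxt``) is provided with an exact float64
round-trip guarantee:

    ALLODYN TRAJ 1
    natoms <N>
    nframes <M>
    frame <k> time <t_ps>
    x y z            # N lines, '%.17g' floats
    ...

No periodic-boundary handling is performed anywhere: trajectories are
assumed whole/imaged before they reach this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .topology import Topology

_MAGIC = "ALLODYN TRAJ 1"


@dataclass
class Trajectory:
    """Cartesian trajectory bound to a topology."""

    coords: np.ndarray   # (n_frames, n_atoms, 3), Å
    times: np.ndarray    # (n_frames,), ps
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if len(self.times) != self.n_frames:
            raise ValueError("one time per frame required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def concatenated(self, *others: "Trajectory") -> "Trajectory":
        """Pool frames from replica trajectories sharing this topology."""
        for o in others:
            if o.topology.n_atoms != self.topology.n_atoms:
                raise ValueError("replicas must share the topology")
        return Trajectory(
            coords=np.concatenate([self.coords] + [o.coords for o in others]),
            times=np.concatenate([self.times] + [o.times for o in others]),
            topology=self.topology,
        )


def write_trjtxt(path, traj: Trajectory) -> None:
    """Write the portable text format ('%.17g' preserves float64 exactly)."""
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        fh.write(f"nframes {traj.n_frames}\n")
        for k in range(traj.n_frames):
            fh.write(f"frame {k} time {traj.times[k]:.17g}\n")
            np.savetxt(fh, traj.coords[k], fmt="%.17g")


def read_trjtxt(path, topology: Topology) -> Trajectory:
    with open(path) as fh:
        if fh.readline().strip() != _MAGIC:
            raise ValueError(f"{path}: not an ALLODYN TRAJ 1 file")
        n_atoms = int(fh.readline().split()[1])
        n_frames = int(fh.readline().split()[1])
        coords = np.empty((n_frames, n_atoms, 3))
        times = np.empty(n_frames)
        for k in range(n_frames):
            header = fh.readline().split()
            times[k] = float(header[3])
            block = [fh.readline().split() for _ in range(n_atoms)]
            coords[k] = np.asarray(block, dtype=float)
    return Trajectory(coords=coords, times=times, topology=topology)


def load_trajectory(path, topology: Topology, pdb_path=None) -> Trajectory:
    """Load a trajectory by extension: .trjtxt (portable), .dcd/.xtc (mdtraj).

    mdtraj needs a topology file for binary formats; pass the matching PDB via
    ``pdb_path``.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".trjtxt":
        return read_trjtxt(path, topology)
    if ext in (".dcd", ".xtc"):
        import mdtraj

        if pdb_path is None:
            raise ValueError(f"{ext} trajectories require pdb_path for the topology")
        mt = mdtraj.load(str(path), top=str(pdb_path))
        if mt.n_atoms != topology.n_atoms:
            raise ValueError("trajectory atom count does not match topology")
        times = mt.time if mt.time is not None else np.arange(mt.n_frames, dtype=float)
        return Trajectory(
            coords=np.asarray(mt.xyz, dtype=float) * 10.0,  # nm -> Å
            times=np.asarray(times, dtype=float),
            topology=topology,
        )
    raise ValueError(f"unsupported trajectory format: {path.suffix!r}")
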