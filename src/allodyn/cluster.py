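"""Conformational clustering of trajectory frames (gromos algorithm).

The gromos algorithm (Daura neighbor counting) operates on a precomputed
pairwise superposed-RMSD matrix: the unassigned frame with the most
neighbors within the cutoff becomes a cluster center; it and its neighbors
form a family and are removed; repeat until every frame is assigned.
Ties on neighbor count are broken toward the lower frame index so the
partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superpose import kabsch_superpose
from .trajectory import Trajectory


@dataclass
class ClusterFamilies:
    """Partition of frames into conformational families, largest first."""

    centers: list[int]            # center frame per family
    members: list[np.ndarray]     # member frame indices per family (center included)
    cutoff: float                 # Å

    @property
    def n_families(self) -> int:
        return len(self.centers)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members]

    def assignments(self, n_frames: int) -> np.ndarray:
        """Per-frame family label (0 = most populated)."""
        lab = np.full(n_frames, -1, dtype=int)
        for fam, m in enumerate(self.members):
            lab[m] = fam
        return lab


def pairwise_rmsd_matrix(traj: Trajectory, fit_selection: np.ndarray,
                         measure_selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric frames × frames matrix of pairwise superposed RMSD (Å).

    Each entry (i, j) superposes frame j onto frame i on ``fit_selection``
    and measures RMSD on ``measure_selection`` (defaults to the fit set,
    matching a gmx-cluster-style combined atom list).
    """
    if traj.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    fit = np.asarray(fit_selection)
    meas = fit if measure_selection is None else np.asarray(measure_selection)
    f = traj.n_frames
    # pre-center the fit coordinates once; Kabsch per ordered pair is then cheap
    x_fit = traj.coords[:, fit, :]
    x_fit = x_fit - x_fit.mean(axis=1, keepdims=True)
    same = meas.shape == fit.shape and np.array_equal(meas, fit)
    x_meas = x_fit if same else traj.coords[:, meas, :] - traj.coords[:, fit, :].mean(axis=1, keepdims=True)

    ii, jj = np.triu_indices(f, k=1)
    # batched Kabsch over all pairs
    h = np.einsum("pki,pkj->pij", x_fit[jj], x_fit[ii])
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pij,pjk->pik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    flip = np.ones((len(ii), 3))
    flip[:, 2] = np.sign(det)
    rot = np.einsum("pji,pj,pkj->pik", vt, flip, u)
    moved = np.einsum("pai,pji->paj", x_meas[jj], rot)
    diff = moved - x_meas[ii]
    vals = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    mat = np.zeros((f, f))
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterFamilies:
    """Cluster frames by iterative neighbor counting on an RMSD matrix.

    Families are returned ordered by decreasing size; ties on size keep
    discovery order (which itself prefers the lower-index center).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("distances must be non-negative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    n = matrix.shape[0]
    neighbor = matrix <= cutoff            # includes self
    unassigned = np.ones(n, dtype=bool)
    centers: list[int] = []
    members: list[np.ndarray] = []
    while unassigned.any():
        counts = (neighbor & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))    # argmax takes the lowest index on ties
        family = np.flatnonzero(neighbor[center] & unassigned)
        centers.append(center)
        members.append(family)
        unassigned[family] = False
    order = sorted(range(len(centers)), key=lambda k: -len(members[k]))
    return ClusterFamilies(
        centers=[centers[k] for k in order],
        members=[members[k] for k in order],
        cutoff=float(cutoff),
    )


def write_cluster_outputs(traj: Trajectory, families: ClusterFamilies, out_dir) -> None:
    """One representative PDB per family (center frame) + frame→family CSV."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lab = families.assignments(traj.n_frames)
    pd.DataFrame({"frame": np.arange(traj.n_frames), "family": lab}).to_csv(
        out / "cluster_assignments.csv", index=False
    )
    for fam, center in enumerate(families.centers):
        traj.topology.to_pdb(out / f"family_{fam}_center_frame{center}.pdb",
                             traj.coords[center])
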