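"""Solvent-accessible surface area (Shrake–Rupley) and contact frequencies.

SASA uses the classic probe-sphere point test: a deterministic
golden-section spiral of ``n_points`` points is placed on each atom's
expanded sphere (vdW radius + probe, default water probe 1.4 Å); the
accessible fraction — points not inside any other atom's expanded sphere —
times the sphere area is the atom's SASA.  The spiral (rather than random
points) makes results exactly reproducible.

Contacts: two residues are in contact in a frame iff any inter-atom
distance between their (heavy, by default) atoms is below the cutoff
(default 4.0 Å); the frequency of occurrence is the fraction of frames in
contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import Topology
from .trajectory import Trajectory


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral: n near-uniform unit vectors."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(coords: np.ndarray, topology: Topology,
                       probe: float = 1.4, n_points: int = 960,
                       include_hydrogens: bool = False) -> np.ndarray:
    """Per-atom SASA (Å²) for one frame.

    Hydrogens are excluded from both the surface and the occluders unless
    ``include_hydrogens``; excluded atoms report 0.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable point density")
    coords = np.asarray(coords, dtype=float)
    active = np.ones(topology.n_atoms, dtype=bool) if include_hydrogens else topology.is_heavy
    idx = np.flatnonzero(active)
    radii = topology.vdw_radii[idx]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = idx[np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0]]
        raise ValueError(
            f"atom {topology.names[bad]} (serial {topology.serials[bad]}) lacks a radius"
        )
    xyz = coords[idx]
    expanded = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(xyz)
    out = np.zeros(topology.n_atoms)
    max_r = expanded.max()
    for a in range(len(idx)):
        # candidate occluders: centers within r_a + max expanded radius
        nb = tree.query_ball_point(xyz[a], expanded[a] + max_r)
        nb = [b for b in nb if b != a]
        surface = xyz[a] + expanded[a] * pts
        if nb:
            d2 = ((surface[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            r2 = (expanded[nb] ** 2)[None, :]
            # points exactly on a neighbor's surface (coincident spheres) are
            # credited to the lower-index atom, not decided by round-off
            eps = 1e-7
            tie = np.array([b < a for b in nb])[None, :]
            buried = ((d2 < r2 - eps) | ((np.abs(d2 - r2) <= eps) & tie)).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[idx[a]] = frac * 4.0 * np.pi * expanded[a] ** 2
    return out


@dataclass
class SasaSeries:
    values: np.ndarray       # per-frame group SASA, Å²
    probe: float
    n_points: int
    times: np.ndarray        # ps


def group_sasa_series(traj: Trajectory, group_selection: np.ndarray,
                      probe: float = 1.4, n_points: int = 960,
                      stride: int = 1,
                      include_hydrogens: bool = False) -> SasaSeries:
    """Per-frame SASA of a residue group, in the context of the whole structure.

    ``stride`` subsamples frames for long trajectories (SASA is the costly
    stage of the pipeline); times are carried along.
    """
    group = np.asarray(group_selection)
    if group.size == 0:
        raise ValueError("group selection is empty")
    frames = np.arange(0, traj.n_frames, stride)
    vals = np.empty(len(frames))
    for k, fr in enumerate(frames):
        per_atom = shrake_rupley_sasa(traj.coords[fr], traj.topology,
                                      probe=probe, n_points=n_points,
                                      include_hydrogens=include_hydrogens)
        vals[k] = per_atom[group].sum()
    return SasaSeries(values=vals, probe=probe, n_points=n_points,
                      times=traj.times[frames])


@dataclass
class ContactTable:
    """Residue-pair contact occurrence frequencies over a trajectory."""

    table: pd.DataFrame      # columns: seq_id_a, seq_id_b, res_a, res_b, frequency
    cutoff: float
    n_frames: int


def contact_frequency(traj: Trajectory, set_a: np.ndarray, set_b: np.ndarray,
                      cutoff: float = 4.0) -> ContactTable:
    """Frequency of occurrence of residue–residue contacts between two atom sets.

    A pair is in contact in a frame iff any inter-atom distance < cutoff.
    ``set_a`` and ``set_b`` must be disjoint at atom level, or identical
    (intra-molecular mode, where pairs within the same residue are skipped).
    Pairs never in contact are omitted.
    """
    a = np.asarray(set_a)
    b = np.asarray(set_b)
    identical = a.shape == b.shape and np.array_equal(a, b)
    if not identical and np.intersect1d(a, b).size:
        raise ValueError("selections overlap but are not identical")
    topo = traj.topology
    res_a, res_b = topo.residue_index[a], topo.residue_index[b]
    counts: dict[tuple[int, int], int] = {}
    for fr in range(traj.n_frames):
        ta = cKDTree(traj.coords[fr, a, :])
        tb = cKDTree(traj.coords[fr, b, :])
        pairs = ta.query_ball_tree(tb, cutoff - 1e-12)
        seen: set[tuple[int, int]] = set()
        for ia, hits in enumerate(pairs):
            for ib in hits:
                ra, rb = int(res_a[ia]), int(res_b[ib])
                if ra == rb:
                    continue
                key = (min(ra, rb), max(ra, rb)) if identical else (ra, rb)
                seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [{
        "seq_id_a": int(topo.res_seq_ids[ra]), "res_a": str(topo.res_names[ra]),
        "seq_id_b": int(topo.res_seq_ids[rb]), "res_b": str(topo.res_names[rb]),
        "frequency": n / traj.n_frames,
    } for (ra, rb), n in counts.items()]
    df = pd.DataFrame(rows, columns=["seq_id_a", "res_a", "seq_id_b", "res_b", "frequency"])
    if len(df):
        df = df.sort_values(["frequency", "seq_id_a", "seq_id_b"],
                            ascending=[False, True, True]).reset_index(drop=True)
    return ContactTable(table=df, cutoff=float(cutoff), n_frames=traj.n_frames)
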