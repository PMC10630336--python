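"""Shared fixtures: tiny hand-built topologies and random rigid motions."""

from __future__ import annotations

import numpy as np
import pytest

from allodyn.topology import Topology


def make_topology(n_res: int, sc_counts=None, seq_origin: int = 1,
                  res_names=None) -> Topology:
    """Toy topology: per residue one CA plus ``sc_counts[i]`` side-chain
    carbons (default none)."""
    sc_counts = sc_counts or [0] * n_res
    names, elements, res_of = [], [], []
    sc_names = ["CB", "CG", "CD", "CE"]
    for i in range(n_res):
        names.append("CA"); elements.append("C"); res_of.append(i)
        for k in range(sc_counts[i]):
            sc = sc_names[k] if k < len(sc_names) else f"CZ{k}"
            names.append(sc); elements.append("C"); res_of.append(i)
    if res_names is None:
        res_names = ["GLY" if c == 0 else "GLU" for c in sc_counts]
    n = len(names)
    return Topology(
        serials=np.arange(1, n + 1),
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        vdw_radii=np.full(n, 1.70),
        residue_index=np.array(res_of),
        res_names=np.array(res_names, dtype=object),
        res_seq_ids=np.arange(seq_origin, seq_origin + n_res),
        chain_ids=np.array(["A"] * n_res, dtype=object),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Apply one rigid motion to a frame or a stack of frames."""
    return coords @ rot.T + trans


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
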