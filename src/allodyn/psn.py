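"""Protein Structure Network (PSN) construction and analysis.

Residues are nodes.  For a residue pair (i, j), n_ij is the time-averaged
number of side-chain heavy-atom pairs (one atom from each residue) within a
distance cutoff (default 4.5 Å).  The interaction strength, in percent, is

    I_ij = n_ij / sqrt(N_i · N_j) × 100,

where N_i and N_j are per-residue-type normalization factors.  A pair is an
edge of the Protein Structure Graph iff I_ij > I_min.  Hubs are
high-degree nodes; communities are connected components of the filtered
graph; communication paths are shortest paths with interaction-strength
tie-breaking.

Normalization factors are either supplied by the user ("user" mode) or
computed from the input ensemble ("empirical" mode, the default): for each
residue type, N is the maximum over residues of that type of the residue's
total time-averaged side-chain contact pairs, floored at 1.  The computed
table is reported so runs are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Trajectory


@dataclass
class PSNGraph:
    """Residue-interaction graph with percent-strength edge weights."""

    graph: nx.Graph                 # nodes: seq_ids; edge attr 'strength' (percent)
    cutoff: float                   # Å
    i_min: float                    # percent
    normalization: dict[str, float] # residue type -> N
    node_labels: dict[int, str]     # seq_id -> 3-letter code

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}


def sidechain_contact_counts(traj: Trajectory, cutoff: float = 4.5) -> pd.DataFrame:
    """Time-averaged n_ij per residue pair (side-chain heavy atoms, strict < cutoff).

    Returns a table (seq_id_a, seq_id_b, n_ij) for pairs with n_ij > 0.
    Residues without side-chain heavy atoms (glycine-like) simply never
    contribute counts.
    """
    topo = traj.topology
    sc = np.flatnonzero(topo.is_heavy & ~topo.is_backbone)
    res_of = topo.residue_index[sc]
    counts: dict[tuple[int, int], float] = {}
    if sc.size:
        for fr in range(traj.n_frames):
            tree = cKDTree(traj.coords[fr, sc, :])
            for ia, ib in tree.query_pairs(cutoff - 1e-12):
                ra, rb = int(res_of[ia]), int(res_of[ib])
                if ra == rb:
                    continue
                key = (min(ra, rb), max(ra, rb))
                counts[key] = counts.get(key, 0.0) + 1.0
    rows = [{
        "seq_id_a": int(topo.res_seq_ids[ra]),
        "seq_id_b": int(topo.res_seq_ids[rb]),
        "n_ij": total / traj.n_frames,
    } for (ra, rb), total in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["seq_id_a", "seq_id_b", "n_ij"])


def empirical_normalization(traj: Trajectory, counts: pd.DataFrame) -> dict[str, float]:
    """N per residue type = max over residues of that type of Σ_j n_ij, floored at 1."""
    topo = traj.topology
    seq_to_name = {int(s): str(n) for s, n in zip(topo.res_seq_ids, topo.res_names)}
    per_res: dict[int, float] = {}
    for row in counts.itertuples(index=False):
        per_res[row.seq_id_a] = per_res.get(row.seq_id_a, 0.0) + row.n_ij
        per_res[row.seq_id_b] = per_res.get(row.seq_id_b, 0.0) + row.n_ij
    table: dict[str, float] = {str(n): 1.0 for n in topo.res_names}
    for seq, total in per_res.items():
        name = seq_to_name[seq]
        table[name] = max(table[name], total)
    return table


def interaction_strength(n_ij: float, table: dict[str, float],
                         res_i: str, res_j: str) -> float:
    """I_ij = n_ij / sqrt(N_i N_j) × 100 (percent)."""
    for r in (res_i, res_j):
        if r not in table:
            raise KeyError(f"residue type {r!r} missing from normalization table")
    return float(n_ij / np.sqrt(table[res_i] * table[res_j]) * 100.0)


def build_psn(traj: Trajectory, cutoff: float = 4.5, i_min: float = 0.0,
              normalization: dict[str, float] | None = None) -> PSNGraph:
    """Build the PSN: edges are residue pairs with I_ij strictly above I_min.

    ``normalization=None`` selects the empirical mode (table computed from
    this trajectory and stored on the result).
    """
    if i_min < 0:
        raise ValueError("I_min must be >= 0")
    topo = traj.topology
    counts = sidechain_contact_counts(traj, cutoff)
    table = empirical_normalization(traj, counts) if normalization is None else dict(normalization)
    seq_to_name = {int(s): str(n) for s, n in zip(topo.res_seq_ids, topo.res_names)}
    g = nx.Graph()
    g.add_nodes_from(int(s) for s in topo.res_seq_ids)
    for row in counts.itertuples(index=False):
        s = interaction_strength(row.n_ij, table,
                                 seq_to_name[row.seq_id_a], seq_to_name[row.seq_id_b])
        if s > i_min:
            g.add_edge(row.seq_id_a, row.seq_id_b, strength=s, n_ij=row.n_ij)
    return PSNGraph(graph=g, cutoff=float(cutoff), i_min=float(i_min),
                    normalization=table, node_labels=seq_to_name)


def hubs(psn: PSNGraph, min_degree: int = 3) -> set[int]:
    """Residues whose PSG degree meets or exceeds ``min_degree``."""
    return {n for n, d in psn.graph.degree if d >= min_degree}


def communities(psn: PSNGraph) -> list[set[int]]:
    """Connected components of the filtered graph, largest first; isolated
    nodes are not communities."""
    comps = [set(c) for c in nx.connected_components(psn.graph) if len(c) > 1]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass
class PathResult:
    connected: bool
    path: list[int] = field(default_factory=list)
    min_strength: float = 0.0


def communication_paths(psn: PSNGraph, source: int, target: int) -> PathResult:
    """Best communication path between two residues.

    Shortest by hop count; ties broken by the greater minimum edge strength
    along the path (the weakest link governs communication), then
    lexicographically.  A disconnected pair yields a PathResult with
    ``connected=False`` rather than an exception.
    """
    g = psn.graph
    for n in (source, target):
        if n not in g:
            raise KeyError(f"residue {n} not in graph")
    if source == target:
        return PathResult(connected=True, path=[source], min_strength=np.inf)
    if not nx.has_path(g, source, target):
        return PathResult(connected=False)
    best: tuple[float, list[int]] | None = None
    for path in nx.all_shortest_paths(g, source, target):
        ms = min(g.edges[u, v]["strength"] for u, v in zip(path, path[1:]))
        if best is None or ms > best[0] + 1e-12 or (
            abs(ms - best[0]) <= 1e-12 and path < best[1]
        ):
            best = (ms, list(path))
    return PathResult(connected=True, path=best[1], min_strength=float(best[0]))


def graph_difference(psn_a: PSNGraph, psn_b: PSNGraph
                     ) -> tuple[set[tuple[int, int]], set[tuple[int, int]], set[tuple[int, int]]]:
    """(edges only in A, edges only in B, shared edges).

    Both graphs must be built over the same residue numbering.
    """
    if set(psn_a.graph.nodes) != set(psn_b.graph.nodes):
        raise ValueError("graphs have mismatched residue numbering")
    ea, eb = psn_a.edge_set(), psn_b.edge_set()
    return ea - eb, eb - ea, ea & eb


def write_psn_outputs(psn: PSNGraph, out_dir, hub_min_degree: int = 3) -> None:
    """Weighted edge-list CSV + GraphML + hubs/communities CSVs + normalization table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"seq_id_a": u, "seq_id_b": v,
             "res_a": psn.node_labels[u], "res_b": psn.node_labels[v],
             "n_ij": d["n_ij"], "strength": d["strength"]}
            for u, v, d in sorted(psn.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["seq_id_a", "seq_id_b", "res_a", "res_b",
                                "n_ij", "strength"]).to_csv(out / "psn_edges.csv",
                                                            index=False)
    nx.write_graphml(psn.graph, out / "psn.graphml")
    pd.DataFrame({"seq_id": sorted(hubs(psn, hub_min_degree))}).to_csv(
        out / "psn_hubs.csv", index=False)
    comm_rows = [{"community": k, "seq_id": n}
                 for k, comp in enumerate(communities(psn)) for n in sorted(comp)]
    pd.DataFrame(comm_rows, columns=["community", "seq_id"]).to_csv(
        out / "psn_communities.csv", index=False)
    pd.DataFrame(sorted(psn.normalization.items()),
                 columns=["res_name", "N"]).to_csv(out / "psn_normalization.csv",
                                                   index=False)
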