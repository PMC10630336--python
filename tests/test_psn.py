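"""Protein structure network: interaction-strength formula, counts oracle,
graph operations vs exhaustive re-derivations."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allodyn.psn import (PSNGraph, build_psn, communication_paths, communities,
                         graph_difference, hubs, interaction_strength,
                         sidechain_contact_counts)
from allodyn.trajectory import Trajectory
from conftest import make_topology


def _traj(coords, topo):
    return Trajectory(coords=coords, times=np.arange(len(coords), dtype=float),
                      topology=topo)


def _psn_from_edges(edges, nodes=None):
    g = nx.Graph()
    g.add_nodes_from(nodes or sorted({n for e in edges for n in e[:2]}))
    for u, v, w in edges:
        g.add_edge(u, v, strength=w, n_ij=w)
    return PSNGraph(graph=g, cutoff=4.5, i_min=0.0, normalization={},
                    node_labels={n: "GLU" for n in g.nodes})


class TestInteractionStrength:
    def test_zero_contacts_zero_strength(self):
        assert interaction_strength(0.0, {"GLU": 4.0}, "GLU", "GLU") == 0.0

    def test_closed_form_value(self):
        # 2 / sqrt(4·4) · 100 = 50
        assert interaction_strength(2.0, {"ALA": 4.0}, "ALA", "ALA") == pytest.approx(50.0)

    def test_hand_computed_cross_types(self):
        # 3 / sqrt(7.5·4.8) · 100 = 3/6 · 100 = 50
        table = {"LEU": 7.5, "SER": 4.8}
        assert interaction_strength(3.0, table, "LEU", "SER") == pytest.approx(50.0)

    def test_missing_type_rejected(self):
        with pytest.raises(KeyError):
            interaction_strength(1.0, {"GLU": 4.0}, "GLU", "TRP")


class TestContactCounts:
    def test_far_residues_zero(self):
        topo = make_topology(2, [2, 2])
        coords = np.zeros((2, 6, 3))
        coords[:, 3:, 0] = 20.0  # second residue 20 Å away
        coords[:, 1, 1] = 1.5; coords[:, 2, 1] = 3.0
        coords[:, 4, 1] = 1.5; coords[:, 5, 1] = 3.0
        df = sidechain_contact_counts(_traj(coords, topo))
        assert len(df) == 0

    def test_constant_pair_count_is_exact(self):
        topo = make_topology(2, [2, 2])
        coords = np.zeros((4, 6, 3))
        coords[:, 1] = [0, 1.5, 0]; coords[:, 2] = [0, 3.0, 0]
        coords[:, 3] = [2, 0, 0]
        coords[:, 4] = [2, 1.5, 0]; coords[:, 5] = [2, 9.0, 0]
        # exactly two side-chain pairs sit within 4.5 Å in every frame:
        # (CB1,CB2) at 2.0 Å and (CG1,CB2) at 2.5 Å
        df = sidechain_contact_counts(_traj(coords, topo), cutoff=4.5)
        assert len(df) == 1
        assert df.n_ij.iloc[0] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng):
        topo = make_topology(5, [2, 0, 3, 1, 2])
        coords = rng.normal(size=(6, topo.n_atoms, 3)) * 3
        traj = _traj(coords, topo)
        df = sidechain_contact_counts(traj, cutoff=4.5)
        got = {(r.seq_id_a, r.seq_id_b): r.n_ij for r in df.itertuples(index=False)}
        sc = [i for i in range(topo.n_atoms)
              if topo.names[i] != "CA"]
        expect: dict = {}
        for f in range(6):
            for a, b in itertools.combinations(sc, 2):
                ra, rb = topo.residue_index[a], topo.residue_index[b]
                if ra == rb:
                    continue
                if np.linalg.norm(coords[f, a] - coords[f, b]) < 4.5:
                    key = (int(topo.res_seq_ids[min(ra, rb)]),
                           int(topo.res_seq_ids[max(ra, rb)]))
                    expect[key] = expect.get(key, 0) + 1 / 6
        assert set(got) == set(expect)
        for k in got:
            assert got[k] == pytest.approx(expect[k])


class TestBuildPsn:
    def _toy_traj(self):
        topo = make_topology(3, [1, 1, 1], seq_origin=10)
        coords = np.zeros((2, 6, 3))
        coords[:, 1] = [0, 1.5, 0]
        coords[:, 2] = [3, 0, 0]; coords[:, 3] = [3, 1.5, 0]
        coords[:, 4] = [6, 0, 0]; coords[:, 5] = [6, 1.5, 0]
        return _traj(coords, topo)

    def test_imin_above_max_gives_edgeless_graph(self):
        psn = build_psn(self._toy_traj(), i_min=1e6)
        assert psn.n_edges == 0

    def test_imin_zero_keeps_every_contacting_pair(self):
        psn = build_psn(self._toy_traj(), i_min=0.0)
        # chain neighbors 3 Å apart touch; 6 Å pair does not
        assert psn.edge_set() == {(10, 11), (11, 12)}

    def test_edge_count_monotone_in_imin_and_cutoff(self, rng):
        topo = make_topology(8, [2] * 8)
        coords = rng.normal(size=(4, topo.n_atoms, 3)) * 4
        traj = _traj(coords, topo)
        counts = [build_psn(traj, i_min=i).n_edges for i in [0, 5, 20, 50, 100]]
        assert counts == sorted(counts, reverse=True)
        by_cutoff = [build_psn(traj, cutoff=c, i_min=1.0).n_edges
                     for c in [2.0, 4.5, 8.0]]
        assert by_cutoff == sorted(by_cutoff)

    def test_frame_reordering_leaves_graph_unchanged(self, rng):
        topo = make_topology(6, [2] * 6)
        coords = rng.normal(size=(5, topo.n_atoms, 3)) * 4
        a = build_psn(_traj(coords, topo), i_min=1.0)
        b = build_psn(_traj(coords[::-1].copy(), topo), i_min=1.0)
        assert a.edge_set() == b.edge_set()

    def test_negative_imin_rejected(self):
        with pytest.raises(ValueError):
            build_psn(self._toy_traj(), i_min=-1.0)


class TestGraphOps:
    def test_hubs_on_star_graph(self):
        psn = _psn_from_edges([(0, k, 10.0) for k in range(1, 6)])
        assert hubs(psn, min_degree=4) == {0}
        assert hubs(_psn_from_edges([], nodes=[1, 2]), 3) == set()

    def test_hubs_match_degree_recount(self, rng):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        psn = _psn_from_edges([(u, v, 1.0) for u, v in g.edges], nodes=g.nodes)
        expect = {n for n in g.nodes
                  if sum(1 for _ in g.neighbors(n)) >= 3}
        assert hubs(psn, 3) == expect

    def test_communities_two_triangles(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                 (5, 6, 1.0), (6, 7, 1.0), (5, 7, 1.0)]
        comms = communities(_psn_from_edges(edges, nodes=range(9)))
        assert [sorted(c) for c in comms] == [[0, 1, 2], [5, 6, 7]]

    def test_communities_match_flood_fill(self, rng):
        g = nx.gnp_random_graph(30, 0.08, seed=9)
        psn = _psn_from_edges([(u, v, 1.0) for u, v in g.edges], nodes=g.nodes)
        # independent flood fill
        seen, comps = set(), []
        for start in g.nodes:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                n = stack.pop()
                if n in comp:
                    continue
                comp.add(n)
                stack.extend(g.neighbors(n))
            seen |= comp
            if len(comp) > 1:
                comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        assert [sorted(c) for c in communities(psn)] == [sorted(c) for c in comps]


class TestPaths:
    def test_source_equals_target(self):
        psn = _psn_from_edges([(0, 1, 5.0)])
        res = communication_paths(psn, 0, 0)
        assert res.connected and res.path == [0]

    def test_linear_chain(self):
        psn = _psn_from_edges([(0, 1, 5.0), (1, 2, 7.0)])
        res = communication_paths(psn, 0, 2)
        assert res.path == [0, 1, 2]

    def test_disconnected_is_a_result_not_an_exception(self):
        psn = _psn_from_edges([(0, 1, 5.0)], nodes=[0, 1, 2])
        res = communication_paths(psn, 0, 2)
        assert not res.connected

    def test_tie_break_matches_exhaustive_enumeration(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            for u, v in g.edges:
                g.edges[u, v]["strength"] = float(np.round(r.uniform(1, 9), 1))
            psn = _psn_from_edges([(u, v, g.edges[u, v]["strength"])
                                   for u, v in g.edges], nodes=g.nodes)
            src, dst = 0, 11
            if not nx.has_path(g, src, dst):
                continue
            # exhaustive: all simple paths, keep the shortest hop count,
            # rank by (min edge strength desc, lexicographic)
            best = None
            short = nx.shortest_path_length(g, src, dst)
            for path in nx.all_simple_paths(g, src, dst, cutoff=short):
                if len(path) - 1 != short:
                    continue
                ms = min(g.edges[u, v]["strength"] for u, v in zip(path, path[1:]))
                key = (-ms, path)
                if best is None or key < best:
                    best = key
            res = communication_paths(psn, src, dst)
            assert res.path == best[1]
            assert res.min_strength == pytest.approx(-best[0])


class TestDifference:
    def test_identical_graphs(self):
        a = _psn_from_edges([(0, 1, 1.0), (1, 2, 1.0)], nodes=range(3))
        b = _psn_from_edges([(0, 1, 1.0), (1, 2, 1.0)], nodes=range(3))
        only_a, only_b, shared = graph_difference(a, b)
        assert not only_a and not only_b and shared == {(0, 1), (1, 2)}

    def test_disjoint_edge_sets(self):
        a = _psn_from_edges([(0, 1, 1.0)], nodes=range(4))
        b = _psn_from_edges([(2, 3, 1.0)], nodes=range(4))
        only_a, only_b, shared = graph_difference(a, b)
        assert only_a == {(0, 1)} and only_b == {(2, 3)} and not shared

    def test_mismatched_numbering_rejected(self):
        a = _psn_from_edges([(0, 1, 1.0)], nodes=range(3))
        b = _psn_from_edges([(0, 1, 1.0)], nodes=range(4))
        with pytest.raises(ValueError):
            graph_difference(a, b)
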