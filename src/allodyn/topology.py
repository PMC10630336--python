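"""Topology data model, PDB I/O and atom selection.

A :class:`Topology` holds the static description of the system — atoms
grouped into residues grouped into chains — as parallel numpy arrays, in
the style of mdtraj/MDAnalysis topologies.  Coordinates live separately in
:class:`allodyn.trajectory.Trajectory`.

Units: Å throughout.  Residue ``seq_id`` values are 1-based PDB numbers and
need not start at 1 (the TPP1 OB-domain, for instance, is numbered from
residue 90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .radii import vdw_radius

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_ATOM_CLASSES = ("all", "heavy", "backbone", "sidechain-heavy", "CA")


class SelectionError(ValueError):
    """Raised when a selection resolves to no atoms or references unknown residues."""


@dataclass
class Topology:
    """Atoms and residues of one molecular system.

    Atom arrays are parallel and ordered; ``residue_index`` maps each atom
    to a row of the residue arrays.
    """

    serials: np.ndarray          # (n_atoms,) int
    names: np.ndarray            # (n_atoms,) str
    elements: np.ndarray         # (n_atoms,) str
    vdw_radii: np.ndarray        # (n_atoms,) float, Å
    residue_index: np.ndarray    # (n_atoms,) int, row into residue arrays
    res_names: np.ndarray        # (n_residues,) 3-letter codes
    res_seq_ids: np.ndarray      # (n_residues,) int, PDB numbering
    chain_ids: np.ndarray        # (n_residues,) str

    def __post_init__(self) -> None:
        self.serials = np.asarray(self.serials, dtype=int)
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.res_seq_ids = np.asarray(self.res_seq_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        if len(np.unique(self.serials)) != self.n_atoms:
            raise ValueError("atom serials must be unique")
        if self.n_atoms and (
            self.residue_index.min() < 0 or self.residue_index.max() >= self.n_residues
        ):
            raise ValueError("every atom must map to an existing residue")
        heavy = self.is_heavy
        if np.any(self.vdw_radii[heavy] <= 0):
            raise ValueError("heavy atoms require positive van der Waals radii")

    # -- derived per-atom flags -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def n_residues(self) -> int:
        return len(self.res_seq_ids)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.array([e.strip().upper() != "H" for e in self.elements], dtype=bool)

    @property
    def is_backbone(self) -> np.ndarray:
        return np.array([n in BACKBONE_NAMES for n in self.names], dtype=bool)

    @property
    def is_ca(self) -> np.ndarray:
        return np.array([n == "CA" for n in self.names], dtype=bool)

    def ca_indices(self) -> np.ndarray:
        """Indices of Cα atoms, in residue order."""
        return np.flatnonzero(self.is_ca)

    def atom_seq_ids(self) -> np.ndarray:
        """Per-atom residue seq_id."""
        return self.res_seq_ids[self.residue_index]

    def seq_id_to_residue(self) -> dict[int, int]:
        return {int(s): i for i, s in enumerate(self.res_seq_ids)}

    # -- PDB I/O (via biotite) --------------------------------------------------

    @classmethod
    def from_pdb(cls, path) -> tuple["Topology", np.ndarray]:
        """Read a PDB file; return (topology, coordinates in Å)."""
        import biotite.structure.io.pdb as pdb

        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        res_starts = np.concatenate(
            [[0], np.flatnonzero(
                (np.diff(arr.res_id) != 0) | (arr.chain_id[1:] != arr.chain_id[:-1])
            ) + 1]
        ) if arr.array_length() else np.array([], dtype=int)
        residue_index = np.zeros(arr.array_length(), dtype=int)
        for ri, start in enumerate(res_starts):
            stop = res_starts[ri + 1] if ri + 1 < len(res_starts) else arr.array_length()
            residue_index[start:stop] = ri
        elements = [e if e else "C" for e in arr.element]
        topo = cls(
            serials=np.arange(1, arr.array_length() + 1),
            names=np.array(list(arr.atom_name), dtype=object),
            elements=np.array(elements, dtype=object),
            vdw_radii=np.array([vdw_radius(e) for e in elements]),
            residue_index=residue_index,
            res_names=np.array([arr.res_name[s] for s in res_starts], dtype=object),
            res_seq_ids=np.array([arr.res_id[s] for s in res_starts], dtype=int),
            chain_ids=np.array([arr.chain_id[s] for s in res_starts], dtype=object),
        )
        return topo, np.asarray(arr.coord, dtype=float)

    def to_pdb(self, path, coords: np.ndarray, b_factors: np.ndarray | None = None,
               occupancies: np.ndarray | None = None) -> None:
        """Write one model with ATOM/TER records; occupancy and B-factor columns honored."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"coords must be ({self.n_atoms}, 3)")
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = coords
        arr.atom_name = np.array([str(n) for n in self.names])
        arr.element = np.array([str(e) for e in self.elements])
        arr.res_name = np.array([str(self.res_names[r]) for r in self.residue_index])
        arr.res_id = np.array([int(self.res_seq_ids[r]) for r in self.residue_index])
        arr.chain_id = np.array([str(self.chain_ids[r]) for r in self.residue_index])
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        arr.set_annotation(
            "b_factor",
            np.zeros(self.n_atoms) if b_factors is None else np.asarray(b_factors, float),
        )
        arr.set_annotation(
            "occupancy",
            np.ones(self.n_atoms) if occupancies is None else np.asarray(occupancies, float),
        )
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))


@dataclass
class SelectionSpec:
    """Declarative atom selection.

    ``ranges`` are inclusive residue seq_id spans, e.g. ``[(165, 184), (210, 215)]``;
    empty means "all residues".  ``atom_class`` is one of ``all``, ``heavy``,
    ``backbone``, ``sidechain-heavy``, ``CA``.  ``names``, if given, further
    restricts to those atom names.
    """

    ranges: list[tuple[int, int]] = field(default_factory=list)
    atom_class: str = "all"
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.atom_class not in _ATOM_CLASSES:
            raise ValueError(
                f"unknown atom_class {self.atom_class!r}; expected one of {_ATOM_CLASSES}"
            )
        self.ranges = [(int(a), int(b)) for a, b in self.ranges]
        for a, b in self.ranges:
            if b < a:
                raise ValueError(f"range ({a}, {b}) has stop < start")


def select(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to a strictly increasing atom index array.

    Raises :class:`SelectionError` if the selection is empty or any requested
    range matches no residue, naming the offending ranges.
    """
    seq = topology.atom_seq_ids()
    if spec.ranges:
        known = set(int(s) for s in topology.res_seq_ids)
        unmatched = [
            (a, b) for a, b in spec.ranges if not any(a <= s <= b for s in known)
        ]
        if unmatched:
            raise SelectionError(f"residue ranges match no residues: {unmatched}")
        in_range = np.zeros(topology.n_atoms, dtype=bool)
        for a, b in spec.ranges:
            in_range |= (seq >= a) & (seq <= b)
    else:
        in_range = np.ones(topology.n_atoms, dtype=bool)

    cls = spec.atom_class
    if cls == "all":
        mask = in_range
    elif cls == "heavy":
        mask = in_range & topology.is_heavy
    elif cls == "backbone":
        mask = in_range & topology.is_backbone
    elif cls == "sidechain-heavy":
        mask = in_range & topology.is_heavy & ~topology.is_backbone
    else:  # CA
        mask = in_range & topology.is_ca

    if spec.names is not None:
        wanted = set(spec.names)
        mask &= np.array([n in wanted for n in topology.names], dtype=bool)

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(
            f"selection is empty (ranges={spec.ranges or 'all'}, "
            f"atom_class={spec.atom_class!r}, names={spec.names})"
        )
    return idx
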