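"""Synthetic protein-like topologies and trajectories with planted ground truth.

The generator emulates the phenomenology a trajectory-analysis pipeline
must recover — nothing physical is simulated:

* a linear Cα chain (3.8 Å spacing) with 0–4 side-chain heavy pseudo-atoms
  per residue;
* inter-region correlated/anti-correlated motions of exact, tunable Pearson
  strength, planted through shared scalar latent factors along a fixed axis;
* two or more conformational sub-states with tunable occupancy, realized as
  a rigid translation of the surface-patch side chains (the "closed" state
  buries the patch against the chain, lowering its SASA);
* intermittent residue–residue contacts with per-frame Bernoulli
  probability;
* optionally one collective "hinge" mode: a residue block moving coherently
  along an axis with Gaussian amplitude;
* isotropic Gaussian noise σ on every atom.

Planted displacement fields are made mean-free over the Cα set at
construction, so the superposition step of downstream analyses cannot
dilute them, and the field amplitude is solved in closed form so the
requested correlation is exact in population.  All randomness flows from a
single seed; identical specs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import Topology
from .trajectory import Trajectory, write_trjtxt

CA_SPACING = 3.8     # Å between consecutive Cα along the chain axis
SC_SPACING = 1.5     # Å between consecutive side-chain pseudo-atoms
HELIX_RADIUS = 2.0   # Å; the Cα trace winds gently so the fold is never
HELIX_PERIOD = 10    # collinear and rigid-body fits are well conditioned
CONTACT_NEAR = 3.0   # Å planted "in contact" distance
CONTACT_FAR = 9.0    # Å planted "no contact" distance

# residue-name palette keyed by side-chain heavy-atom count
_PALETTE = {0: "GLY", 1: "ALA", 2: "SER", 3: "VAL", 4: "GLU"}
_SC_NAMES = ["CB", "CG", "CD", "CE"]


class InfeasiblePlanError(ValueError):
    """The correlation plan implies a non-realizable (non-PSD) covariance."""


@dataclass
class StatePlan:
    """One conformational sub-state of the surface patch.

    ``sidechain_contraction`` scales the patch side-chain offsets from their
    Cα (1.0 = fully extended/open; small values collapse the side chains
    onto the backbone, burying the patch).  ``patch_displacement`` is an
    additional rigid translation of the patch side chains.
    """

    label: str
    occupancy: float
    patch_displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Å
    sidechain_contraction: float = 1.0


@dataclass
class ModePlan:
    """Collective hinge block: residues [start, stop] move along ``axis``
    with N(0, amplitude²) loading per frame."""

    start: int
    stop: int
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    amplitude: float = 1.0  # Å


@dataclass
class PlantSpec:
    n_residues: int = 130
    seq_origin: int = 90
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    patch_seq_ids: list[int] = field(default_factory=list)
    correlation_plan: list[tuple[str, str, float]] = field(default_factory=list)
    state_plan: list[StatePlan] = field(default_factory=list)
    contact_plan: list[tuple[int, int, float]] = field(default_factory=list)
    mode_plan: ModePlan | None = None
    noise_sigma: float = 0.1   # Å
    n_frames: int = 1000
    seed: int = 0
    sidechain_count: int | None = None  # fixed count per residue (else 0-4 random)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if self.state_plan:
            occ = sum(s.occupancy for s in self.state_plan)
            if not np.isclose(occ, 1.0):
                raise ValueError(f"state occupancies must sum to 1, got {occ}")
        for a, b, rho in self.correlation_plan:
            if not (-1.0 < rho < 1.0):
                raise InfeasiblePlanError(f"correlation {rho} for ({a},{b}) not in (-1, 1)")
            for r in (a, b):
                if r not in self.regions:
                    raise ValueError(f"correlation plan names unknown region {r!r}")
        seen: set[str] = set()
        for a, b, _ in self.correlation_plan:
            if a in seen or b in seen or a == b:
                raise InfeasiblePlanError(
                    "each region may appear in at most one correlation-plan entry"
                )
            seen.update((a, b))
        spans = sorted(self.regions.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("regions must be disjoint")

    def seq_ids(self) -> np.ndarray:
        return np.arange(self.seq_origin, self.seq_origin + self.n_residues)


def tpp1like_spec(n_frames: int = 1000, seed: int = 0, **overrides) -> PlantSpec:
    """Preset mimicking the TPP1 OB-domain bookkeeping: 130 residues numbered
    90–219, regions I/II/III, TEL-patch-like surface group.  Numbering only;
    no structural realism is claimed."""
    kwargs = dict(
        n_residues=130,
        seq_origin=90,
        regions={"I": (123, 141), "II": (158, 178), "III": (207, 219)},
        patch_seq_ids=[168, 169, 171, 183, 212, 215],
        correlation_plan=[("I", "II", -0.5)],
        state_plan=[
            StatePlan("open", 0.7),
            # closed: side chains collapsed onto the backbone and tucked toward
            # the helix interior — buries the patch and separates the states
            # well beyond the 1.8 Å cluster threshold
            StatePlan("closed", 0.3, (0.0, 0.0, -2.0), 0.25),
        ],
        contact_plan=[(100, 150, 0.4)],
        noise_sigma=0.1,
        n_frames=n_frames,
        seed=seed,
    )
    kwargs.update(overrides)
    return PlantSpec(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator planted, as realized in the emitted frames."""

    state_labels: list[str]                              # per frame
    state_occupancy: dict[str, float]                    # realized fractions
    requested_correlations: dict[str, float]             # "A|B" -> rho
    realized_correlations: dict[str, float]              # "A|B" -> mean sample C_ij
    contact_events: dict[str, list[int]]                 # "a|b" -> 0/1 per frame
    realized_contact_frequency: dict[str, float]
    mode_block_seq_ids: list[int]                        # hinge block (empty if none)
    mode_vector: list[float]                             # 3N unit vector over Cα
    seed: int

    def to_json(self) -> str:
        return json.dumps({"schema_version": 1, **dataclasses.asdict(self)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d.pop("schema_version", None)
        return cls(**d)


def generate_topology(spec: PlantSpec) -> tuple[Topology, np.ndarray]:
    """Build the chain topology and its base-fold coordinates (Å).

    Deterministic given ``spec.seed``.  Patch residues always get 4
    side-chain atoms pointing +y (so the planted burial direction is well
    defined); contact-plan residues get at least 2.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    seq_ids = spec.seq_ids()
    patch = set(spec.patch_seq_ids)
    contact_res = {s for a, b, _ in spec.contact_plan for s in (a, b)}

    names, elements, res_of, coords = [], [], [], []
    res_names = []
    for i, seq in enumerate(seq_ids):
        if spec.sidechain_count is not None:
            n_sc = spec.sidechain_count
        else:
            n_sc = int(rng.integers(0, 5))
        if seq in patch:
            n_sc = 4
        elif seq in contact_res:
            n_sc = max(n_sc, 2)
        phi = np.pi / 2 if seq in patch else float(rng.uniform(0, 2 * np.pi))
        res_names.append(_PALETTE[n_sc])
        turn = 2.0 * np.pi * i / HELIX_PERIOD
        ca = np.array([CA_SPACING * i,
                       HELIX_RADIUS * np.cos(turn),
                       HELIX_RADIUS * np.sin(turn)])
        names.append("CA"); elements.append("C"); res_of.append(i); coords.append(ca)
        direction = np.array([0.0, np.cos(phi), np.sin(phi)])
        for k in range(n_sc):
            names.append(_SC_NAMES[k]); elements.append("C"); res_of.append(i)
            coords.append(ca + direction * SC_SPACING * (k + 1))
    coords = np.asarray(coords)
    topo = Topology(
        serials=np.arange(1, len(names) + 1),
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        vdw_radii=np.full(len(names), 1.70),
        residue_index=np.array(res_of, dtype=int),
        res_names=np.array(res_names, dtype=object),
        res_seq_ids=seq_ids,
        chain_ids=np.array(["A"] * spec.n_residues, dtype=object),
    )
    return topo, coords


def _field_amplitude(p: float, q: float, rho: float, sigma: float) -> float:
    """Solve g = a² so that g·p·q / sqrt((g p²+3σ²)(g q²+3σ²)) = rho exactly.

    p and q are the mean-free field weights of the two regions.  Raises when
    the requested sign cannot be realized or a weight vanishes.
    """
    if rho == 0.0:
        return 0.0
    if abs(p) < 1e-12 or abs(q) < 1e-12:
        raise InfeasiblePlanError("degenerate region weights; correlation not plantable")
    if np.sign(p * q) != np.sign(rho):
        raise InfeasiblePlanError("requested correlation sign is not realizable")
    s2 = 3.0 * sigma * sigma
    a_coef = (1.0 - rho * rho) * p * p * q * q
    b_coef = -rho * rho * s2 * (p * p + q * q)
    c_coef = -rho * rho * s2 * s2
    g = (-b_coef + np.sqrt(b_coef * b_coef - 4.0 * a_coef * c_coef)) / (2.0 * a_coef)
    return float(g)


def generate_trajectory(topology: Topology, spec: PlantSpec,
                        base_coords: np.ndarray | None = None
                        ) -> tuple[Trajectory, GroundTruth]:
    """Emit the frames and the record of everything that was planted."""
    if base_coords is None:
        _, base_coords = generate_topology(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    n_frames, n_atoms, n_res = spec.n_frames, topology.n_atoms, topology.n_residues
    seq_ids = topology.res_seq_ids
    seq_to_res = topology.seq_id_to_residue()
    atoms_of_res = [np.flatnonzero(topology.residue_index == r) for r in range(n_res)]
    ca_of_res = topology.ca_indices()

    # --- sub-states -----------------------------------------------------------
    if spec.state_plan:
        occ = np.array([s.occupancy for s in spec.state_plan])
        state_idx = rng.choice(len(spec.state_plan), size=n_frames, p=occ)
    else:
        state_idx = np.zeros(n_frames, dtype=int)
    labels = ([spec.state_plan[k].label for k in state_idx]
              if spec.state_plan else ["base"] * n_frames)

    # --- planted correlated fields (mean-free over Cα) -------------------------
    entries = []
    for name_a, name_b, rho in spec.correlation_plan:
        (a0, a1), (b0, b1) = spec.regions[name_a], spec.regions[name_b]
        in_a = (seq_ids >= a0) & (seq_ids <= a1)
        in_b = (seq_ids >= b0) & (seq_ids <= b1)
        s = np.sign(rho) if rho != 0 else 1.0
        w = np.where(in_a, 1.0, np.where(in_b, s, 0.0))
        c = w.mean()
        w = w - c                      # superposition-proof: zero mean over Cα
        entries.append((name_a, name_b, rho, w, 1.0 - c, s - c))
    if len(entries) > 1:
        # fields with a nonzero centroid correction leak a shared background term
        # into every residue; with several latents that bias has no closed form,
        # so multi-entry plans must use balanced (equal-size, anti-correlated) pairs
        for name_a, name_b, rho, w, p, q in entries:
            if rho != 0.0 and abs(p - 1.0) > 1e-9:
                raise InfeasiblePlanError(
                    "multiple correlation entries require balanced "
                    "(equal-size, anti-correlated) region pairs"
                )

    disp_res = np.zeros((n_frames, n_res, 3))   # per-residue planted displacement
    realized_requested: dict[str, float] = {}
    for name_a, name_b, rho, w, p, q in entries:
        realized_requested[f"{name_a}|{name_b}"] = rho
        if rho == 0.0:
            continue
        amp = np.sqrt(_field_amplitude(p, q, rho, spec.noise_sigma))
        # the field points along the chain axis: the Cα lie on that axis, so the
        # field carries no torque and the rotation part of a downstream
        # superposition cannot absorb it (translation is killed by mean-freeing)
        axis = np.array([1.0, 0.0, 0.0])
        latent = rng.normal(size=n_frames)
        disp_res += amp * latent[:, None, None] * w[None, :, None] * axis[None, None, :]

    # --- collective hinge mode --------------------------------------------------
    mode_block: list[int] = []
    mode_vec = np.zeros(3 * n_res)
    if spec.mode_plan is not None:
        mp = spec.mode_plan
        in_block = (seq_ids >= mp.start) & (seq_ids <= mp.stop)
        if not in_block.any():
            raise ValueError("mode plan matches no residues")
        axis = np.asarray(mp.axis, dtype=float)
        axis /= np.linalg.norm(axis)
        latent = rng.normal(size=n_frames)
        disp_res += mp.amplitude * latent[:, None, None] * in_block[None, :, None] * axis
        mode_block = [int(s) for s in seq_ids[in_block]]
        v = (in_block[:, None] * axis[None, :]).ravel()
        mode_vec = v / np.linalg.norm(v)

    # --- assemble frames ----------------------------------------------------------
    coords = np.repeat(base_coords[None, :, :], n_frames, axis=0)
    # rigid per-residue planted displacement (all atoms of the residue move together)
    for r in range(n_res):
        coords[:, atoms_of_res[r], :] += disp_res[:, r, None, :]
    # state geometry: patch side-chain atoms only (Cα untouched, so backbone
    # metrics and planted correlations are unaffected)
    if spec.state_plan and spec.patch_seq_ids:
        offsets = np.array([s.patch_displacement for s in spec.state_plan])
        contraction = np.array([s.sidechain_contraction for s in spec.state_plan])
        for s in spec.patch_seq_ids:
            res_atoms = atoms_of_res[seq_to_res[s]]
            ca_atom = res_atoms[0]
            sc_atoms = [a for a in res_atoms if topology.names[a] != "CA"]
            if not sc_atoms:
                continue
            rel = base_coords[sc_atoms] - base_coords[ca_atom]   # (k, 3)
            scale = contraction[state_idx] - 1.0                 # (F,)
            coords[:, sc_atoms, :] += (scale[:, None, None] * rel[None, :, :]
                                       + offsets[state_idx][:, None, :])
    # isotropic noise everywhere
    coords += rng.normal(0.0, spec.noise_sigma, size=(n_frames, n_atoms, 3))

    # --- planted intermittent contacts (override one side-chain atom) -------------
    contact_events: dict[str, list[int]] = {}
    realized_freq: dict[str, float] = {}
    for seq_a, seq_b, prob in spec.contact_plan:
        ra, rb = seq_to_res[seq_a], seq_to_res[seq_b]
        sc_a = [a for a in atoms_of_res[ra] if topology.names[a] != "CA"]
        sc_b = [a for a in atoms_of_res[rb] if topology.names[a] != "CA"]
        if not sc_a or not sc_b:
            raise ValueError(f"contact plan pair ({seq_a},{seq_b}) needs side chains")
        on = (rng.random(n_frames) < prob).astype(int)
        u = np.array([0.0, 0.0, 1.0])
        dist = np.where(on == 1, CONTACT_NEAR, CONTACT_FAR)
        coords[:, sc_b[-1], :] = coords[:, sc_a[0], :] + dist[:, None] * u[None, :]
        key = f"{seq_a}|{seq_b}"
        contact_events[key] = on.tolist()
        realized_freq[key] = float(on.mean())

    # --- realized correlations (direct Pearson on the emitted Cα series) ----------
    realized: dict[str, float] = {}
    if entries:
        ca_disp = coords[:, ca_of_res, :] - coords[:, ca_of_res, :].mean(axis=0)
        var = np.einsum("fia,fia->i", ca_disp, ca_disp) / n_frames
        for name_a, name_b, rho, w, p, q in entries:
            (a0, a1), (b0, b1) = spec.regions[name_a], spec.regions[name_b]
            ia = np.flatnonzero((seq_ids >= a0) & (seq_ids <= a1))
            ib = np.flatnonzero((seq_ids >= b0) & (seq_ids <= b1))
            num = np.einsum("fia,fja->ij", ca_disp[:, ia, :], ca_disp[:, ib, :]) / n_frames
            cij = num / np.sqrt(np.outer(var[ia], var[ib]))
            realized[f"{name_a}|{name_b}"] = float(cij.mean())

    truth = GroundTruth(
        state_labels=list(labels),
        state_occupancy={lab: labels.count(lab) / n_frames for lab in dict.fromkeys(labels)},
        requested_correlations=realized_requested,
        realized_correlations=realized,
        contact_events=contact_events,
        realized_contact_frequency=realized_freq,
        mode_block_seq_ids=mode_block,
        mode_vector=mode_vec.tolist(),
        seed=spec.seed,
    )
    traj = Trajectory(coords=coords, times=np.arange(n_frames, dtype=float),
                      topology=topology)
    return traj, truth


def emit_fixture_bundle(spec: PlantSpec, out_dir) -> dict[str, Path]:
    """Write PDB + portable trajectory + ground-truth JSON + analysis config.

    The bundle round-trips through the package's own readers and is directly
    consumable by ``allodyn run``.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo, base = generate_topology(spec)
    traj, truth = generate_trajectory(topo, spec, base)

    paths = {
        "pdb": out / "system.pdb",
        "traj": out / "trajectory.trjtxt",
        "truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    topo.to_pdb(paths["pdb"], base)
    write_trjtxt(paths["traj"], traj)
    paths["truth"].write_text(truth.to_json())

    lo, hi = int(spec.seq_origin), int(spec.seq_origin + spec.n_residues - 1)
    patch = [int(s) for s in spec.patch_seq_ids] or [lo]
    # cluster on the Cα of the patch-bearing regions plus the patch side chains
    # (a whole-chain Cα set would dilute the sub-state signal)
    patch_regions = [[int(a), int(b)] for a, b in spec.regions.values()
                     if any(a <= s <= b for s in patch)] or [[lo, hi]]
    config = {
        "topology": str(paths["pdb"]),
        "trajectories": [str(paths["traj"])],
        "selections": {
            "fit": {"atom_class": "CA"},
            "rmsd": {"atom_class": "CA"},
            "cluster": [
                {"ranges": patch_regions, "atom_class": "CA"},
                {"ranges": [[s, s] for s in patch], "atom_class": "sidechain-heavy"},
            ],
            "patch_group": {"ranges": [[s, s] for s in patch], "atom_class": "heavy"},
        },
        "regions": {k: [int(v[0]), int(v[1])] for k, v in spec.regions.items()},
        "parameters": {
            "cluster_cutoff": 1.8,
            "correlation_threshold": 0.6,
            "sasa_probe": 1.4,
            "sasa_points": 960,
            "sasa_stride": 10,
            "contact_cutoff": 4.0,
            "psn_cutoff": 4.5,
            "i_min": 1.0,
            "hub_min_degree": 3,
        },
        "seed": int(spec.seed),
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
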