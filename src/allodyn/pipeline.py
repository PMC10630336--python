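"""End-to-end analysis pipeline.

``run_analysis`` executes every stage on each configured system — RMSD/RMSF,
gromos clustering, essential-dynamics PCA, cross-correlation, SASA of the
patch group, contact frequencies, and the protein structure network — then
compares systems (PSN difference, RMSF overlay).  Replicas of a system are
concatenated before analysis.  Any stage failure aborts with the stage name
and the cause.  Outputs are plain CSV/PDB/GraphML with fixed float
formatting, so identical inputs give byte-identical reports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import gromos_cluster, pairwise_rmsd_matrix, write_cluster_outputs
from .config import AnalysisConfig
from .dccm import cross_correlation_matrix, write_dccm_outputs
from .edpca import essential_dynamics, write_projection_outputs
from .psn import PSNGraph, build_psn, graph_difference, write_psn_outputs
from .surface import contact_frequency, group_sasa_series
from .superpose import rmsf
from .topology import SelectionSpec, Topology, select
from .trajectory import Trajectory, load_trajectory

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, system: str, stage: str, cause: Exception):
        self.system, self.stage, self.cause = system, stage, cause
        super().__init__(f"[{system}] stage {stage!r} failed: {cause}")


def _union_selection(topology: Topology, specs: list[SelectionSpec]) -> np.ndarray:
    idx: set[int] = set()
    for spec in specs:
        idx.update(int(i) for i in select(topology, spec))
    return np.array(sorted(idx), dtype=int)


def _load_system(sys_input, cfg: AnalysisConfig) -> Trajectory:
    topo, _ = Topology.from_pdb(sys_input.topology)
    trajs = [load_trajectory(p, topo, pdb_path=sys_input.topology)
             for p in sys_input.trajectories]
    return trajs[0] if len(trajs) == 1 else trajs[0].concatenated(*trajs[1:])


def run_analysis(cfg: AnalysisConfig) -> Path:
    """Run every stage; return the output directory.

    Layout: ``<out>/<system>/…`` per system, comparison tables and
    ``run_log.txt`` at the top level.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.parameters
    psn_graphs: dict[str, PSNGraph] = {}
    rmsf_tables: dict[str, pd.DataFrame] = {}
    norm_tables: dict[str, dict[str, float]] = {}

    for sys_input in cfg.systems:
        name = sys_input.name
        sdir = out / name
        sdir.mkdir(parents=True, exist_ok=True)

        def run_stage(stage, fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, stage, exc) from exc

        traj = run_stage("load", lambda: _load_system(sys_input, cfg))
        topo = traj.topology
        fit, meas, clus_sel = run_stage("selections", lambda: (
            _union_selection(topo, cfg.selections["fit"]),
            _union_selection(topo, cfg.selections["rmsd"]),
            _union_selection(topo, cfg.selections["cluster"]),
        ))

        # RMSD vs first frame
        def _rmsd():
            from .superpose import rmsd as rmsd_series
            series = rmsd_series(traj, 0, fit, meas)
            pd.DataFrame({"time_ps": traj.times, "rmsd_A": series}).to_csv(
                sdir / "rmsd.csv", index=False, float_format=_FLOAT_FMT)
        run_stage("rmsd", _rmsd)

        # per-residue RMSF on Cα
        def _rmsf():
            ca = topo.ca_indices()
            vals = rmsf(traj, fit, ca)
            df = pd.DataFrame({
                "seq_id": topo.res_seq_ids[topo.residue_index[ca]],
                "rmsf_A": vals,
            })
            df.to_csv(sdir / "rmsf.csv", index=False, float_format=_FLOAT_FMT)
            rmsf_tables[name] = df
        run_stage("rmsf", _rmsf)

        # gromos clustering
        def _cluster():
            mat = pairwise_rmsd_matrix(traj, clus_sel)
            fams = gromos_cluster(mat, p["cluster_cutoff"])
            write_cluster_outputs(traj, fams, sdir)
        run_stage("cluster", _cluster)

        # essential dynamics PCA
        def _pca():
            ca = topo.ca_indices()
            modes = essential_dynamics(traj, ca, fit)
            write_projection_outputs(traj, ca, modes, sdir, mode_index=1)
        run_stage("pca", _pca)

        # cross-correlation matrix + region summary
        def _dccm():
            ca = topo.ca_indices()
            m = cross_correlation_matrix(traj, ca, fit)
            write_dccm_outputs(m, sdir, threshold=p["correlation_threshold"],
                               regions=cfg.regions or None)
        run_stage("dccm", _dccm)

        # SASA of the patch group
        if "patch_group" in cfg.selections:
            def _sasa():
                group = _union_selection(topo, cfg.selections["patch_group"])
                series = group_sasa_series(
                    traj, group, probe=p["sasa_probe"],
                    n_points=int(p["sasa_points"]), stride=int(p["sasa_stride"]))
                pd.DataFrame({"time_ps": series.times, "sasa_A2": series.values}).to_csv(
                    sdir / "patch_sasa.csv", index=False, float_format=_FLOAT_FMT)
            run_stage("sasa", _sasa)

        # heavy-atom contact frequencies (intra-molecular)
        def _contacts():
            heavy = np.flatnonzero(topo.is_heavy)
            table = contact_frequency(traj, heavy, heavy, cutoff=p["contact_cutoff"])
            table.table.to_csv(sdir / "contacts.csv", index=False,
                               float_format=_FLOAT_FMT)
        run_stage("contacts", _contacts)

        # protein structure network
        def _psn():
            g = build_psn(traj, cutoff=p["psn_cutoff"], i_min=p["i_min"])
            write_psn_outputs(g, sdir, hub_min_degree=int(p["hub_min_degree"]))
            psn_graphs[name] = g
            norm_tables[name] = g.normalization
        run_stage("psn", _psn)

    # cross-system comparisons
    names = [s.name for s in cfg.systems]
    if len(names) >= 2:
        rows = []
        ref = names[0]
        for other in names[1:]:
            only_a, only_b, shared = graph_difference(psn_graphs[ref], psn_graphs[other])
            rows.append({"system_a": ref, "system_b": other,
                         "edges_a": psn_graphs[ref].n_edges,
                         "edges_b": psn_graphs[other].n_edges,
                         "unique_a": len(only_a), "unique_b": len(only_b),
                         "shared": len(shared)})
        pd.DataFrame(rows).to_csv(out / "psn_difference.csv", index=False)
        overlay = rmsf_tables[names[0]][["seq_id"]].copy()
        for n in names:
            overlay[f"rmsf_{n}"] = rmsf_tables[n]["rmsf_A"].values
        overlay.to_csv(out / "rmsf_overlay.csv", index=False, float_format=_FLOAT_FMT)

    # run log: every parameter actually used (no timestamps: reports must be
    # byte-stable across reruns)
    with open(out / "run_log.txt", "w") as log:
        log.write(f"allodyn {__version__}\n")
        log.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        log.write(f"seed: {cfg.seed}\n")
        for k in sorted(p):
            log.write(f"parameter {k} = {p[k]:.10g}\n")
        for name, sel in sorted(cfg.selections.items()):
            log.write(f"selection {name}: {sel}\n")
        for name, span in sorted(cfg.regions.items()):
            log.write(f"region {name}: {span[0]}-{span[1]}\n")
        for name, table in sorted(norm_tables.items()):
            for res, val in sorted(table.items()):
                log.write(f"normalization[{name}] {res} = {val:.10g}\n")
        for w in cfg.warnings:
            log.write(f"warning: {w}\n")
    return out
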