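"""Dynamical cross-correlation matrix (DCCM) between residue pairs.

For each residue the 3-D displacement of its Cα from the time mean,
δr_i(t) = r_i(t) − ⟨r_i⟩, is taken after superposing all frames onto the
iterated mean structure (all analyzed Cα as the fit set).  The correlation
is the Pearson coefficient of the 3-D displacement vectors,

    C_ij = ⟨δr_i · δr_j⟩ / sqrt(⟨|δr_i|²⟩ ⟨|δr_j|²⟩),

with time averages over all (pooled) frames.  C_ij ∈ [−1, 1]; +1 means the
pair moves in lockstep, −1 in exact opposition.  Values beyond ±threshold
(default 0.6, strict inequality) are classified as strong/anti correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superpose import iterated_mean_structure
from .trajectory import Trajectory


@dataclass
class CorrelationMatrix:
    values: np.ndarray        # (N, N) in [-1, 1]
    seq_ids: np.ndarray       # residue labels (PDB numbering)
    res_names: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def cross_correlation_matrix(traj: Trajectory, ca_selection: np.ndarray,
                             fit_selection: np.ndarray | None = None
                             ) -> CorrelationMatrix:
    """Residue–residue Pearson correlation of Cα displacement vectors.

    Raises if any residue has zero displacement variance (its correlation
    is undefined), naming the residue.
    """
    if traj.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    ca = np.asarray(ca_selection)
    fit = ca if fit_selection is None else np.asarray(fit_selection)
    fitted, mean = iterated_mean_structure(traj, fit)
    disp = fitted[:, ca, :] - fitted[:, ca, :].mean(axis=0)   # (F, N, 3)
    # numerator: time average of the 3-D dot product for every pair
    num = np.einsum("fia,fja->ij", disp, disp) / traj.n_frames
    var = np.einsum("fia,fia->i", disp, disp) / traj.n_frames
    res_idx = traj.topology.residue_index[ca]
    # variance below ~ (3e-8 Å)² is superposition round-off, not motion
    tiny = 1e-15
    if np.any(var <= tiny):
        bad = int(np.flatnonzero(var <= tiny)[0])
        seq = traj.topology.res_seq_ids[res_idx[bad]]
        name = traj.topology.res_names[res_idx[bad]]
        raise ValueError(f"residue {name}{seq} has zero displacement variance")
    c = num / np.sqrt(np.outer(var, var))
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(
        values=c,
        seq_ids=traj.topology.res_seq_ids[res_idx],
        res_names=traj.topology.res_names[res_idx],
    )


def classify_correlations(matrix: CorrelationMatrix, threshold: float = 0.6) -> np.ndarray:
    """Label matrix: 'strong' iff C_ij > threshold, 'anti' iff C_ij < −threshold,
    else 'none'; the diagonal is excluded ('none')."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    c = matrix.values
    lab = np.full(c.shape, "none", dtype=object)
    lab[c > threshold] = "strong"
    lab[c < -threshold] = "anti"
    np.fill_diagonal(lab, "none")
    return lab


def region_block_summary(matrix: CorrelationMatrix,
                         regions: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Mean correlation over cross pairs for each pair of named regions.

    ``regions`` maps a name to an inclusive seq_id range.  Regions must be
    disjoint.  Returns a table with columns (region_a, region_b, mean_c,
    n_pairs, sign).
    """
    masks: dict[str, np.ndarray] = {}
    for name, (a, b) in regions.items():
        masks[name] = (matrix.seq_ids >= a) & (matrix.seq_ids <= b)
        if not masks[name].any():
            raise ValueError(f"region {name!r} ({a}-{b}) matches no residues")
    names = list(regions)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if (masks[names[i]] & masks[names[j]]).any():
                raise ValueError(f"regions {names[i]!r} and {names[j]!r} overlap")
    rows = []
    for i in range(len(names)):
        for j in range(i, len(names)):
            ma, mb = masks[names[i]], masks[names[j]]
            block = matrix.values[np.ix_(ma, mb)]
            if i == j:
                # within a region, skip the unit diagonal
                off = ~np.eye(block.shape[0], dtype=bool)
                vals = block[off]
            else:
                vals = block.ravel()
            mean = float(vals.mean()) if vals.size else np.nan
            rows.append({
                "region_a": names[i], "region_b": names[j],
                "mean_c": mean, "n_pairs": int(vals.size),
                "sign": "anti" if mean < 0 else ("positive" if mean > 0 else "zero"),
            })
    return pd.DataFrame(rows)


def write_dccm_outputs(matrix: CorrelationMatrix, out_dir,
                       threshold: float = 0.6,
                       regions: dict[str, tuple[int, int]] | None = None) -> None:
    """Matrix CSV, classification CSV and optional region summary CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = [f"{n}{s}" for n, s in zip(matrix.res_names, matrix.seq_ids)]
    pd.DataFrame(matrix.values, index=labels, columns=labels).to_csv(out / "dccm.csv")
    pd.DataFrame(classify_correlations(matrix, threshold),
                 index=labels, columns=labels).to_csv(out / "dccm_classified.csv")
    if regions:
        region_block_summary(matrix, regions).to_csv(out / "dccm_region_summary.csv",
                                                     index=False)
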