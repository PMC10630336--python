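"""Essential-dynamics PCA of Cα fluctuations.

The trajectory is superposed onto its iterated mean structure, the 3N × 3N
covariance matrix of Cartesian Cα displacements is diagonalized, and the
leading eigenvectors describe the slowest, largest-amplitude collective
motions.  The per-residue modulus of an eigenvector (norm of its x,y,z
sub-vector at each residue) maps a mode onto the sequence — residues that
carry a mode stand out.  No mass weighting; coordinates in Å, eigenvalues
in Å².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superpose import iterated_mean_structure
from .trajectory import Trajectory


@dataclass
class EssentialModes:
    eigenvalues: np.ndarray    # (3N,), Å², descending
    eigenvectors: np.ndarray   # (3N, 3N), column k = mode k, unit norm
    mean_structure: np.ndarray # (N, 3), Å

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def variance_fraction(self, k: int = 0) -> float:
        """Fraction of total fluctuation variance carried by mode ``k``."""
        tot = self.eigenvalues.sum()
        return float(self.eigenvalues[k] / tot) if tot > 0 else 0.0


def covariance_matrix(traj: Trajectory, ca_selection: np.ndarray,
                      fit_selection: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Covariance of Cα displacements after iterated-mean superposition.

    Entry (3i+a, 3j+b) is Cov(displacement component a of atom i,
    component b of atom j).  Returns (covariance (3N, 3N), mean (N, 3)).
    ``fit_selection`` defaults to the analyzed Cα set.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    ca = np.asarray(ca_selection)
    fit = ca if fit_selection is None else np.asarray(fit_selection)
    fitted, mean = iterated_mean_structure(traj, fit)
    disp = (fitted[:, ca, :] - mean[ca]).reshape(traj.n_frames, -1)
    disp = disp - disp.mean(axis=0)
    cov = disp.T @ disp / traj.n_frames
    return cov, mean[ca]


def pca_modes(cov: np.ndarray, mean_structure: np.ndarray | None = None) -> EssentialModes:
    """Eigendecomposition of a displacement covariance matrix.

    Eigenvalues are clipped at 0 (covariance is PSD up to round-off) and
    sorted descending.  Sign convention: the largest-magnitude component of
    each eigenvector is made positive, so the decomposition is deterministic.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    for k in range(v.shape[1]):
        lead = np.argmax(np.abs(v[:, k]))
        if v[lead, k] < 0:
            v[:, k] = -v[:, k]
    n = cov.shape[0] // 3
    if mean_structure is None:
        mean_structure = np.zeros((n, 3))
    return EssentialModes(eigenvalues=w, eigenvectors=v,
                          mean_structure=np.asarray(mean_structure, dtype=float))


def residue_projection(modes: EssentialModes, mode_index: int = 1) -> np.ndarray:
    """Per-residue modulus of an eigenvector (1-based ``mode_index``).

    Value for residue i is the Euclidean norm of the mode's (x, y, z)
    sub-vector at atom i; the squared values sum to 1 because eigenvectors
    are unit norm.
    """
    if not (1 <= mode_index <= modes.n_modes):
        raise IndexError(f"mode_index {mode_index} out of range 1..{modes.n_modes}")
    vec = modes.eigenvectors[:, mode_index - 1].reshape(-1, 3)
    return np.linalg.norm(vec, axis=1)


def essential_dynamics(traj: Trajectory, ca_selection: np.ndarray,
                       fit_selection: np.ndarray | None = None) -> EssentialModes:
    """Convenience wrapper: covariance + eigendecomposition in one call."""
    cov, mean = covariance_matrix(traj, ca_selection, fit_selection)
    return pca_modes(cov, mean)


def write_projection_outputs(traj: Trajectory, ca_selection: np.ndarray,
                             modes: EssentialModes, out_dir, mode_index: int = 1) -> None:
    """CSV of per-residue projections + B-factor-annotated mean-structure PDB
    (B = projection × 100) for structure-viewer coloring."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proj = residue_projection(modes, mode_index)
    ca = np.asarray(ca_selection)
    res_idx = traj.topology.residue_index[ca]
    pd.DataFrame({
        "seq_id": traj.topology.res_seq_ids[res_idx],
        "res_name": traj.topology.res_names[res_idx],
        f"mode{mode_index}_projection": proj,
    }).to_csv(out / f"pca_mode{mode_index}_projection.csv", index=False)

    b = np.zeros(traj.topology.n_atoms)
    per_res = {int(r): p * 100.0 for r, p in zip(res_idx, proj)}
    for a in range(traj.topology.n_atoms):
        b[a] = per_res.get(int(traj.topology.residue_index[a]), 0.0)
    coords = traj.coords.mean(axis=0)
    coords[ca] = modes.mean_structure
    traj.topology.to_pdb(out / f"pca_mode{mode_index}_bfactor.pdb", coords, b_factors=b)
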