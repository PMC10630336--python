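"""Rigid-body superposition (Kabsch), RMSD and RMSF.

All fits are unweighted least squares on a fit selection; the resulting
rigid transform is applied to the whole frame.  Rotations are always proper
(determinant +1): reflections are never returned, even for planar or
mirror-degenerate inputs.  No mass weighting is used anywhere.
"""

from __future__ import annotations

import numpy as np

from .trajectory import Trajectory


class DegenerateFitError(ValueError):
    """Fit selection is too small or (near-)collinear to define a rotation."""


def _check_fit_set(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    # collinear points leave <2 significant singular values
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear; rotation is ill-defined")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_selection: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superpose one frame onto a reference.

    Parameters
    ----------
    mobile, reference : (n_atoms, 3) arrays, Å.
    fit_selection : atom indices used for the fit (default: all atoms).

    Returns
    -------
    (transformed, rotation, translation) such that
    ``transformed = (mobile - com_mobile) @ rotation.T + com_reference`` and
    ``translation = com_reference - com_mobile @ rotation.T``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(mobile.shape[0]) if fit_selection is None else np.asarray(fit_selection)
    m_fit, r_fit = mobile[idx], reference[idx]
    _check_fit_set(m_fit)
    _check_fit_set(r_fit)
    com_m, com_r = m_fit.mean(axis=0), r_fit.mean(axis=0)
    h = (m_fit - com_m).T @ (r_fit - com_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transformed = (mobile - com_m) @ rot.T + com_r
    translation = com_r - rot @ com_m
    return transformed, rot, translation


def superpose_frames(coords: np.ndarray, reference: np.ndarray,
                     fit_selection: np.ndarray) -> np.ndarray:
    """Superpose every frame of a (F, n, 3) stack onto a reference frame.

    Vectorized batched-SVD Kabsch; rotations are forced proper per frame.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.asarray(fit_selection)
    _check_fit_set(reference[idx])
    m_fit = coords[:, idx, :]                       # (F, k, 3)
    r_fit = reference[idx]                          # (k, 3)
    com_m = m_fit.mean(axis=1, keepdims=True)       # (F, 1, 3)
    com_r = r_fit.mean(axis=0)
    h = np.einsum("fki,kj->fij", m_fit - com_m, r_fit - com_r)  # (F, 3, 3)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    flip = np.ones((len(coords), 3))
    flip[:, 2] = np.sign(det)
    rot = np.einsum("fji,fj,fkj->fik", vt, flip, u)  # V diag(1,1,d) U^T per frame
    out = np.einsum("fai,fji->faj", coords - com_m, rot) + com_r
    return out


def rmsd(traj: Trajectory, reference_frame: int, fit_selection: np.ndarray,
         measure_selection: np.ndarray) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame after fitting on ``fit_selection``.

    The reference frame's own RMSD is exactly zero; all values are >= 0.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.coords[reference_frame]
    fitted = superpose_frames(traj.coords, ref, np.asarray(fit_selection))
    diff = fitted[:, np.asarray(measure_selection), :] - ref[np.asarray(measure_selection)]
    out = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    out[reference_frame] = 0.0
    return out


def iterated_mean_structure(traj: Trajectory, fit_selection: np.ndarray,
                            n_iter: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Superpose to a self-consistent mean structure.

    Frames are fitted to the first frame, the mean is computed, frames are
    refitted to that mean and the mean recomputed (``n_iter`` passes).  This
    is the standard essential-dynamics reference; returns
    (fitted coords (F, n, 3), mean structure (n, 3)).
    """
    fit_selection = np.asarray(fit_selection)
    fitted = superpose_frames(traj.coords, traj.coords[0], fit_selection)
    mean = fitted.mean(axis=0)
    for _ in range(n_iter):
        fitted = superpose_frames(traj.coords, mean, fit_selection)
        mean = fitted.mean(axis=0)
    return fitted, mean


def rmsf(traj: Trajectory, fit_selection: np.ndarray,
         measure_selection: np.ndarray) -> np.ndarray:
    """Root-mean-square fluctuation (Å) of each measured atom about the
    iterated-mean structure after superposition.

    With one Cα per residue in ``measure_selection`` this is the per-residue
    fluctuation profile.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted, mean = iterated_mean_structure(traj, fit_selection)
    m = np.asarray(measure_selection)
    d = fitted[:, m, :] - mean[m]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))
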