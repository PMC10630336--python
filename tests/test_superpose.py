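"""Kabsch superposition, RMSD and RMSF against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allodyn.superpose import (DegenerateFitError, kabsch_superpose, rmsd, rmsf,
                               superpose_frames)
from allodyn.trajectory import Trajectory
from conftest import apply_rigid, make_topology, random_rotation


def brute_force_fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over rotation angles numerically."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def f(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        d = m @ rot.T - r
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = np.inf
    rng = np.random.default_rng(7)
    for _ in range(40):
        res = minimize(f, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def frame_rmsd(a, b, fit, meas):
    t, _, _ = kabsch_superpose(a, b, fit)
    d = t[meas] - b[meas]
    return np.sqrt(np.mean(np.sum(d * d, axis=1)))


class TestKabsch:
    def test_identical_frames_zero_rmsd(self, rng):
        x = rng.normal(size=(10, 3))
        t, rot, _ = kabsch_superpose(x, x)
        assert np.allclose(t, x, atol=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-12)

    def test_rigid_motion_exactly_removed(self, rng):
        x = rng.normal(size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = apply_rigid(x, rot90, np.array([5.0, 5.0, 5.0]))
        t, _, _ = kabsch_superpose(moved, x)
        assert np.sqrt(np.mean(np.sum((t - x) ** 2, axis=1))) < 1e-12

    def test_matches_brute_force_minimum(self, rng):
        x = rng.normal(size=(10, 3)) * 3
        y = x.copy()
        y[4] += np.array([1.0, 0.0, 0.0])  # one atom displaced 1 Å
        fitted = frame_rmsd(y, x, np.arange(10), np.arange(10))
        oracle = brute_force_fit_rmsd(y, x)
        assert fitted == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("shape", ["random", "planar", "mirror"])
    def test_rotation_always_proper(self, rng, shape):
        x = rng.normal(size=(8, 3))
        if shape == "planar":
            x[:, 2] = 0.0
        y = -x if shape == "mirror" else rng.normal(size=(8, 3))
        if shape == "planar":
            y = x @ Rotation.from_euler("z", 30, degrees=True).as_matrix().T
        _, rot, _ = kabsch_superpose(y, x)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_fit_set_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line, line)

    def test_too_few_atoms_rejected(self, rng):
        x = rng.normal(size=(2, 3))
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(x, x)


def _traj_from_coords(coords):
    topo = make_topology(coords.shape[1])
    return Trajectory(coords=coords, times=np.arange(len(coords), dtype=float),
                      topology=topo)


class TestRmsd:
    def test_static_trajectory_all_zero(self, rng):
        frame = rng.normal(size=(6, 3)) * 4
        traj = _traj_from_coords(np.repeat(frame[None], 5, axis=0))
        out = rmsd(traj, 0, np.arange(6), np.arange(6))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_single_atom_displacement_definition(self, rng):
        frame = rng.normal(size=(8, 3)) * 4
        moved = frame.copy()
        moved[7] += np.array([0.0, 2.0, 0.0])
        traj = _traj_from_coords(np.stack([frame, moved]))
        out = rmsd(traj, 0, fit_selection=np.arange(7),
                   measure_selection=np.array([7]))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(2.0, abs=1e-10)

    def test_per_frame_matches_bruteforce_recomputation(self, rng):
        coords = rng.normal(size=(12, 9, 3)) * 3
        # two-state flavor: half the frames share an offset on atoms 0-3
        coords[6:, :4, :] += 2.5
        traj = _traj_from_coords(coords)
        fit, meas = np.arange(9), np.arange(9)
        series = rmsd(traj, 0, fit, meas)
        for f in range(12):
            assert series[f] == pytest.approx(
                frame_rmsd(coords[f], coords[0], fit, meas), abs=1e-10)

    def test_reference_out_of_range(self, rng):
        traj = _traj_from_coords(rng.normal(size=(3, 5, 3)))
        with pytest.raises(IndexError):
            rmsd(traj, 5, np.arange(5), np.arange(5))

    def test_symmetry_between_two_frames(self, rng):
        a, b = rng.normal(size=(2, 10, 3)) * 3
        sel = np.arange(10)
        assert frame_rmsd(a, b, sel, sel) == pytest.approx(
            frame_rmsd(b, a, sel, sel), abs=1e-10)


class TestRmsf:
    def test_static_trajectory_zero(self, rng):
        frame = rng.normal(size=(6, 3)) * 4
        traj = _traj_from_coords(np.repeat(frame[None], 4, axis=0))
        assert np.allclose(rmsf(traj, np.arange(6), np.arange(6)), 0.0, atol=1e-12)

    def test_single_frame_rejected(self, rng):
        traj = _traj_from_coords(rng.normal(size=(1, 6, 3)))
        with pytest.raises(ValueError):
            rmsf(traj, np.arange(6), np.arange(6))

    def test_oscillating_residue_closed_form(self, rng):
        base = rng.normal(size=(8, 3)) * 5
        n_frames = 64
        disp = 0.7 * np.sin(2 * np.pi * np.arange(n_frames) / 16)
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 5, 0] += disp
        traj = _traj_from_coords(coords)
        out = rmsf(traj, fit_selection=np.array([0, 1, 2, 3, 4, 6, 7]),
                   measure_selection=np.array([5]))
        expected = np.sqrt(np.mean((disp - disp.mean()) ** 2))
        assert out[0] == pytest.approx(expected, rel=1e-9)

    def test_isotropic_jitter_gives_sigma_sqrt3(self, rng):
        # 3-D Gaussian jitter of width σ per axis has RMSF σ√3 in expectation;
        # the system is large enough that the 6 rigid DOF the fit removes
        # (a factor 1 - 6/3N on the variance) stay inside the 5% band
        sigma = 0.2
        n_atoms = 100
        base = rng.normal(size=(n_atoms, 3)) * 10
        coords = base[None] + rng.normal(scale=sigma, size=(5000, n_atoms, 3))
        traj = _traj_from_coords(coords)
        out = rmsf(traj, np.arange(n_atoms), np.arange(n_atoms))
        assert np.allclose(out, sigma * np.sqrt(3), rtol=0.05)


class TestRigidMotionInvariance:
    def test_rmsd_and_rmsf_invariant_under_global_rigid_motion(self, rng):
        coords = rng.normal(size=(10, 8, 3)) * 3
        traj = _traj_from_coords(coords)
        sel = np.arange(8)
        base_rmsd = rmsd(traj, 0, sel, sel)
        base_rmsf = rmsf(traj, sel, sel)
        for _ in range(10):
            rot, trans = random_rotation(rng), rng.normal(size=3) * 20
            moved = _traj_from_coords(apply_rigid(coords, rot, trans))
            assert np.allclose(rmsd(moved, 0, sel, sel), base_rmsd, atol=1e-8)
            assert np.allclose(rmsf(moved, sel, sel), base_rmsf, atol=1e-8)

    def test_batch_superpose_matches_single(self, rng):
        coords = rng.normal(size=(6, 7, 3)) * 3
        ref = rng.normal(size=(7, 3)) * 3
        sel = np.arange(7)
        batch = superpose_frames(coords, ref, sel)
        for f in range(6):
            single, _, _ = kabsch_superpose(coords[f], ref, sel)
            assert np.allclose(batch[f], single, atol=1e-10)
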