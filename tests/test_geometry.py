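"""Distance traces, iron displacement, Kabsch RMSD and stacking geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hemegate.geometry import (
    DistanceTrace,
    StackingCutoffs,
    distance_trace,
    iron_plane_displacement,
    kabsch_rmsd,
    mean_distance,
    rmsd_trace,
    stacking_geometry,
)
from hemegate.structure_io import Trajectory, read_trajectory


def _static_traj(positions_nm, n_frames=5, spacing=0.2):
    base = np.asarray(positions_nm, dtype=float)
    return Trajectory(
        times=np.arange(n_frames) * spacing,
        coordinates=np.tile(base, (n_frames, 1, 1)),
        frame_spacing=spacing,
    )


def _random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestDistanceTrace:
    def test_static_pair(self):
        traj = _static_traj([[0.0, 0.0, 0.0], [0.45, 0.0, 0.0]])
        trace = distance_trace(traj, 0, 1)
        assert np.allclose(trace.values, 0.45)

    def test_atom_with_itself_is_zero(self):
        traj = _static_traj([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        assert np.allclose(distance_trace(traj, 0, 0).values, 0.0)

    def test_matches_naive_per_frame_recomputation(self, rng):
        coords = rng.normal(0, 1, size=(20, 6, 3))
        traj = Trajectory(times=np.arange(20) * 0.2, coordinates=coords)
        trace = distance_trace(traj, 1, 4)
        naive = np.array([np.linalg.norm(coords[k, 1] - coords[k, 4]) for k in range(20)])
        # agreement to the last ulp (vectorized vs per-frame norm differ only
        # in floating-point summation order)
        assert np.allclose(trace.values, naive, rtol=1e-13, atol=0.0)

    def test_planted_gating_series_recovered(self, small_system):
        rep = small_system.replicates[0]
        traj = read_trajectory(small_system.model, rep.trajectory_path)
        from hemegate.structure_io import resolve_site

        i_ne = resolve_site(small_system.model, small_system.site_map, "alpha", "E7", "NE2",
                            chain_id="A")
        i_fe = small_system.model.heme_for_chain("A").fe_index
        trace = distance_trace(traj, i_ne, i_fe)
        assert np.max(np.abs(trace.values - rep.gate_series["A"])) <= 1e-3

    def test_minimum_image_mode(self):
        traj = _static_traj([[0.2, 0.0, 0.0], [9.8, 0.0, 0.0]])
        plain = distance_trace(traj, 0, 1)
        wrapped = distance_trace(traj, 0, 1, box_lengths=(10.0, 10.0, 10.0))
        assert np.allclose(plain.values, 9.6)
        assert np.allclose(wrapped.values, 0.4)


class TestMeanDistance:
    def test_constant_trace(self):
        trace = DistanceTrace("c", np.arange(100) * 0.2, np.full(100, 0.21))
        assert mean_distance(trace, 1.0, 19.0) == pytest.approx(0.21)

    def test_alternating_symmetry(self):
        values = np.tile([0.2, 0.3], 50)
        trace = DistanceTrace("alt", np.arange(100) * 0.2, values)
        assert mean_distance(trace, 0.0, 19.9) == pytest.approx(0.25)

    def test_empty_window_raises(self):
        trace = DistanceTrace("c", np.arange(10) * 0.2, np.full(10, 0.2))
        with pytest.raises(ValueError):
            mean_distance(trace, 5.0, 6.0)

    def test_planted_ou_mean_within_3_se(self, small_system):
        rep = small_system.replicates[0]
        series = rep.fe_l1_series["A"]
        n_eff = len(series) * 0.2 / (2 * small_system.spec.fe_l1_tau)  # OU decorrelation
        se = small_system.spec.fe_l1_sd / np.sqrt(n_eff)
        assert abs(series.mean() - small_system.spec.fe_l1_mean_alpha) <= 3 * se


class TestIronDisplacement:
    PYRROLE = np.array([[0.1, 0, 0], [0, 0.1, 0], [-0.1, 0, 0], [0, -0.1, 0]])

    def _traj(self, fe, prox, pyrrole=None):
        pts = np.vstack([[fe], pyrrole if pyrrole is not None else self.PYRROLE, [prox]])
        return _static_traj(pts, n_frames=1)

    def test_fe_at_centroid_is_zero(self):
        traj = self._traj([0, 0, 0], [0, 0, 1])
        disp = iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5)
        assert disp.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_analytic_offset_case(self):
        traj = self._traj([0, 0, 0.04], [0, 0, 1])
        disp = iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5)
        assert disp.values[0] == pytest.approx(0.04, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        base = np.vstack([[[0, 0, 0.04]], self.PYRROLE, [[0, 0, 1.0]]])
        for _ in range(10):
            rot = _random_rotation(rng)
            shift = rng.normal(0, 5, 3)
            moved = base @ rot.T + shift
            traj = _static_traj(moved, n_frames=1)
            disp = iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5)
            # independent recomputation: |Fe - centroid| with the known sign
            centroid = moved[1:5].mean(axis=0)
            assert disp.values[0] == pytest.approx(np.linalg.norm(moved[0] - centroid), abs=1e-12)
            assert disp.values[0] == pytest.approx(0.04, abs=1e-9)

    def test_sign_flips_with_proximal_reference(self):
        up = self._traj([0, 0, 0.04], [0, 0, 1])
        down = self._traj([0, 0, 0.04], [0, 0, -1])
        d_up = iron_plane_displacement(up, 0, [1, 2, 3, 4], 5).values[0]
        d_down = iron_plane_displacement(down, 0, [1, 2, 3, 4], 5).values[0]
        assert d_up == pytest.approx(-d_down)

    def test_signed_magnitude_bounded_by_fe_centroid_distance(self, rng):
        for _ in range(20):
            pyrrole = self.PYRROLE + rng.normal(0, 0.01, (4, 3))
            fe = rng.normal(0, 0.05, 3)
            traj = self._traj(fe, [0, 0, 1], pyrrole)
            disp = iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5)
            centroid = pyrrole.mean(axis=0)
            assert abs(disp.values[0]) <= np.linalg.norm(fe - centroid) + 1e-12
            assert disp.perpendicular[0] <= abs(disp.values[0]) + 1e-12

    def test_collinear_nitrogens_rejected(self):
        pyrrole = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0], [0.4, 0, 0]])
        traj = self._traj([0, 0, 0.04], [0, 0, 1], pyrrole)
        with pytest.raises(ValueError, match="collinear"):
            iron_plane_displacement(traj, 0, [1, 2, 3, 4], 5)


def _bruteforce_min_rmsd(ref, mob):
    """Independent numerical minimum over proper rotations (grid + refinement)."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for ax in np.eye(3):
        for ang in grid:
            res = minimize(cost, ax * ang, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
            best = min(best, res.fun)
    return best


class TestKabschRMSD:
    def test_identity(self, rng):
        x = rng.normal(0, 1, (10, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_gives_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (8, 3))
        rot = _random_rotation(rng)
        t = rng.normal(0, 10, 3)
        assert kabsch_rmsd(x, x @ rot.T + t) <= 1e-10

    def test_single_displaced_atom_matches_bruteforce(self, rng):
        x = rng.normal(0, 1, (6, 3))
        y = x.copy()
        y[2] += [0.3, -0.1, 0.2]
        assert kabsch_rmsd(x, y) == pytest.approx(_bruteforce_min_rmsd(x, y), abs=1e-6)

    def test_agrees_with_mdanalysis(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        for _ in range(5):
            x = rng.normal(0, 1, (9, 3))
            y = x + rng.normal(0, 0.1, (9, 3))
            assert kabsch_rmsd(x, y) == pytest.approx(
                mda_rmsd(y, x, center=True, superposition=True), abs=1e-10
            )

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDTrace:
    def test_static_trajectory_is_zero(self):
        traj = _static_traj(np.random.default_rng(0).normal(0, 1, (6, 3)), n_frames=5)
        trace = rmsd_trace(traj, 0, list(range(6)))
        assert np.all(trace.values <= 1e-12)

    def test_pure_rigid_motion_is_zero(self, rng):
        base = rng.normal(0, 1, (7, 3))
        frames = []
        for _ in range(6):
            frames.append(base @ _random_rotation(rng).T + rng.normal(0, 3, 3))
        traj = Trajectory(times=np.arange(6) * 0.2, coordinates=np.array(frames))
        trace = rmsd_trace(traj, 0, list(range(7)))
        assert np.all(trace.values <= 1e-9)

    def test_planted_isotropic_scaling_matches_closed_form(self, rng):
        # scaling all atoms radially by (1 + c t) leaves rotation optimal at
        # identity, so RMSD(t) = c t sqrt(mean |r_i|^2) exactly
        base = rng.normal(0, 1, (10, 3))
        base -= base.mean(axis=0)
        c = 0.01
        times = np.arange(10) * 0.2
        frames = np.array([(1 + c * t) * base for t in times])
        traj = Trajectory(times=times, coordinates=frames)
        trace = rmsd_trace(traj, 0, list(range(10)))
        expected = c * times * np.sqrt(np.mean(np.sum(base**2, axis=1)))
        assert np.allclose(trace.values, expected, atol=1e-10)


class TestStackingGeometry:
    @staticmethod
    def _ring(center, normal, radius=0.14, n=6):
        normal = np.asarray(normal, float)
        normal /= np.linalg.norm(normal)
        a = np.cross(normal, [1.0, 0.3, 0.2])
        a /= np.linalg.norm(a)
        b = np.cross(normal, a)
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.asarray(center) + radius * (np.outer(np.cos(ang), a) + np.outer(np.sin(ang), b))

    def test_parallel_displaced(self):
        g = stacking_geometry(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([0.15, 0, 0.38], [0, 0, 1]))
        assert g.stacking_class == "parallel-displaced"
        assert g.centroid_distance == pytest.approx(np.hypot(1.5, 3.8), abs=1e-6)
        assert g.interplanar_angle == pytest.approx(0.0, abs=1e-6)
        assert g.offset == pytest.approx(1.5, abs=1e-6)

    def test_t_shaped(self):
        g = stacking_geometry(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([0, 0, 0.5], [1, 0, 0]))
        assert g.stacking_class == "T-shaped"
        assert g.interplanar_angle == pytest.approx(90.0, abs=1e-6)

    def test_far_parallel_is_none(self):
        g = stacking_geometry(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([0, 0, 0.8], [0, 0, 1]))
        assert g.stacking_class == "none"

    def test_nonplanar_ring_rejected(self, rng):
        bent = self._ring([0, 0, 0], [0, 0, 1])
        bent[:, 2] += rng.normal(0, 0.08, len(bent))
        with pytest.raises(ValueError, match="planar"):
            stacking_geometry(bent, self._ring([0, 0, 0.4], [0, 0, 1]))

    def test_custom_cutoffs(self):
        tight = StackingCutoffs(parallel_max_distance=3.0)
        g = stacking_geometry(self._ring([0, 0, 0], [0, 0, 1]),
                              self._ring([0.15, 0, 0.38], [0, 0, 1]), cutoffs=tight)
        assert g.stacking_class == "none"
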