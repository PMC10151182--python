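import numpy as np
import pytest
from scipy import signal as sps

from gridtheta import synthcohort as sc
from gridtheta.errors import InvalidArgumentError
from gridtheta.navio import TrajectoryLog


def _fixed_kin(bout=2.0, pause=2.0, **kw):
    return sc.KinematicsSpec(
        bout_duration=sc.DurationDist(bout, kind="fixed"),
        pause_duration=sc.DurationDist(pause, kind="fixed"), **kw)


def _bout_runs(traj):
    padded = np.concatenate([[False], traj.moving, [False]]).astype(int)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


class TestTrajectory:
    def test_deterministic_schedule_ten_bouts(self):
        traj = sc.simulate_trajectory(sc.ArenaSpec(), _fixed_kin(), 40.0, seed=1)
        runs = _bout_runs(traj)
        assert len(runs) == 10
        rate = traj.sample_rate
        for s, e in runs:
            assert (e - s) / rate == pytest.approx(2.0)
            # each bout preceded by >= 2 s recorded immobility
            assert not traj.moving[max(0, s - int(2 * rate)):s].any()

    def test_seed_determinism(self):
        kin = sc.KinematicsSpec()
        a = sc.simulate_trajectory(sc.ArenaSpec(), kin, 60.0, seed=42)
        b = sc.simulate_trajectory(sc.ArenaSpec(), kin, 60.0, seed=42)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.heading, b.heading)
        np.testing.assert_array_equal(a.moving, b.moving)

    def test_straight_bout_displacement_bound(self):
        # 2 s bout at top speed 5: <= 10 vm and >= 10 minus the accel deficit
        kin = _fixed_kin(top_speed=5.0, accel_time=0.3)
        traj = sc.simulate_trajectory(sc.ArenaSpec(), kin, 8.0, seed=3)
        s, e = _bout_runs(traj)[0]
        p0 = np.array([traj.x[s - 1], traj.y[s - 1]])
        p1 = np.array([traj.x[e - 1], traj.y[e - 1]])
        d = np.linalg.norm(p1 - p0)
        assert d <= 10.0 + 1e-6
        assert d >= 10.0 - kin.top_speed * kin.accel_time

    @pytest.mark.parametrize("seed", range(5))
    def test_positions_stay_inside_arena(self, seed):
        arena = sc.ArenaSpec(side_length=40.0)  # small arena forces reflections
        traj = sc.simulate_trajectory(arena, sc.KinematicsSpec(), 120.0, seed=seed)
        assert traj.x.min() >= 0 and traj.x.max() <= 40.0
        assert traj.y.min() >= 0 and traj.y.max() <= 40.0

    def test_moving_iff_translational_speed_positive(self):
        traj = sc.simulate_trajectory(sc.ArenaSpec(), sc.KinematicsSpec(), 60.0, seed=5)
        step = np.hypot(np.diff(traj.x), np.diff(traj.y))
        np.testing.assert_array_equal(step > 1e-12, traj.moving[1:])

    def test_invalid_duration(self):
        with pytest.raises(InvalidArgumentError):
            sc.simulate_trajectory(sc.ArenaSpec(), sc.KinematicsSpec(), -1.0, 0)


class TestVoxelSeries:
    def test_noiseless_envelope_constant_during_movement(self):
        traj = sc.simulate_trajectory(sc.ArenaSpec(), _fixed_kin(bout=4.0), 30.0, seed=1)
        osc = sc.OscillatorSpec(n_voxels=1, grid_voxel_index=0, grid_gain=0.0,
                                noise_amp=0.0)
        vox = sc.simulate_voxel_series(traj, osc, seed=0)
        env = np.abs(sps.hilbert(vox.values[0]))
        idx = np.searchsorted(traj.t, vox.times)
        idx = np.clip(idx, 0, traj.t.size - 1)
        moving = traj.moving[idx]
        # interior movement samples (0.6 s past onset to skip the ramp edge)
        runs_on = np.flatnonzero(moving & ~np.concatenate([[False], moving[:-1]]))
        sel = np.zeros_like(moving)
        for s in runs_on:
            sel[s + 120:s + 120 + 400] = True
        sel &= moving
        assert env[sel] == pytest.approx(osc.base_amp + osc.movement_gain, rel=0.02)

    def test_grid_modulation_envelope_ratio(self):
        # movement along phi vs phi+30: envelope ratio (b+m+g)/(b+m-g)
        segs = [(False, 2.0, 0.0), (True, 4.0, 20.0), (False, 2.0, 0.0),
                (True, 4.0, 50.0), (False, 2.0, 0.0)]
        from conftest import make_traj
        traj = make_traj(segs, rate=50.0)
        osc = sc.OscillatorSpec(n_voxels=1, grid_voxel_index=0, grid_gain=0.5,
                                grid_orientation=20.0, noise_amp=0.0)
        vox = sc.simulate_voxel_series(traj, osc, seed=0)
        env = np.abs(sps.hilbert(vox.values[0]))
        t = vox.times
        env_on = np.median(env[(t > 3.0) & (t < 5.5)])    # aligned bout
        env_off = np.median(env[(t > 9.0) & (t < 11.5)])  # anti-aligned bout
        expected = (1 + 1 + 0.5) / (1 + 1 - 0.5)
        assert env_on / env_off == pytest.approx(expected, rel=0.02)

    def test_only_grid_voxel_modulated(self):
        traj = sc.simulate_trajectory(sc.ArenaSpec(), sc.KinematicsSpec(), 30.0, seed=2)
        osc = sc.OscillatorSpec(n_voxels=3, grid_voxel_index=1, noise_amp=0.0)
        vox = sc.simulate_voxel_series(traj, osc, seed=0)
        assert not np.allclose(vox.values[1], vox.values[0])
        np.testing.assert_allclose(vox.values[0], vox.values[2])

    def test_amplitude_invariant_enforced(self):
        with pytest.raises(InvalidArgumentError):
            sc.OscillatorSpec(base_amp=1.0, movement_gain=1.0, grid_gain=2.5)

    def test_noise_psd_slope(self):
        traj = sc.simulate_trajectory(sc.ArenaSpec(), sc.KinematicsSpec(), 120.0, seed=0)
        for exponent in (0.5, 1.0):
            osc = sc.OscillatorSpec(n_voxels=1, grid_voxel_index=0, base_amp=0.0,
                                    movement_gain=0.0, grid_gain=0.0,
                                    noise_amp=1.0, noise_exponent=exponent)
            vox = sc.simulate_voxel_series(traj, osc, seed=1)
            f, pxx = sps.welch(vox.values[0], fs=200.0, nperseg=4096)
            sel = (f >= 2.0) & (f <= 70.0)
            slope = np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)[0]
            assert slope == pytest.approx(-exponent, abs=0.2)


class TestBehavior:
    def test_trial_counts_per_block(self):
        df = sc.simulate_behavior(sc.ArenaSpec(), 5.0, 3, seed=0)
        assert (df["phase"] == "retrieval").sum() == 96  # 32 per environment
        assert (df["phase"] == "encoding").sum() == 24   # 8 per environment
        per_block = df[df["phase"] == "retrieval"].groupby("block").size()
        assert (per_block == 32).all()

    def test_zero_error_scale_exact_recall(self):
        df = sc.simulate_behavior(sc.ArenaSpec(), 0.0, 2, seed=1)
        np.testing.assert_array_equal(df["resp_x"], df["true_x"])
        np.testing.assert_array_equal(df["resp_y"], df["true_y"])

    def test_mean_distance_matches_rayleigh_closed_form(self):
        scale = 5.0
        dfs = [sc.simulate_behavior(sc.ArenaSpec(), scale, 50, seed=s)
               for s in range(4)]
        d = np.concatenate([
            np.hypot(df["resp_x"] - df["true_x"], df["resp_y"] - df["true_y"])
            [df["phase"] == "retrieval"] for df in dfs])
        assert d.mean() == pytest.approx(sc.mean_error_distance(scale), rel=0.03)


class TestCohort:
    def _small_spec(self, **kw):
        osc = sc.OscillatorSpec(n_voxels=1, grid_voxel_index=0)
        defaults = dict(n_blocks=1, block_duration_s=20.0, oscillator=osc, seed=9)
        defaults.update(kw)
        return sc.CohortSpec(**defaults)

    def test_default_group_sizes_and_labels(self, tmp_path):
        spec = self._small_spec()  # default 23 controls + 17 patients
        dirs = sc.simulate_cohort(spec, tmp_path / "cohort")
        assert len(dirs) == 40
        groups = [sc.read_participant(d).group for d in dirs]
        assert groups.count("control") == 23
        assert groups.count("patient") == 17

    def test_patients_have_zero_grid_gain(self, tmp_path):
        spec = self._small_spec(n_controls=2, n_patients=3)
        dirs = sc.simulate_cohort(spec, tmp_path / "c")
        for d in dirs:
            p = sc.read_participant(d)
            if p.group == "patient":
                assert p.truth["grid_gain"] == 0.0

    def test_truth_sidecars_byte_identical_across_runs(self, tmp_path):
        spec = self._small_spec(n_controls=2, n_patients=2)
        d1 = sc.simulate_cohort(spec, tmp_path / "run1")
        d2 = sc.simulate_cohort(spec, tmp_path / "run2")
        for a, b in zip(d1, d2):
            assert (a / "truth.yaml").read_bytes() == (b / "truth.yaml").read_bytes()
            assert (a / "trajectory.csv").read_bytes() == (b / "trajectory.csv").read_bytes()

    def test_round_trip_participant(self, tmp_path):
        spec = self._small_spec(n_controls=2, n_patients=2)
        dirs = sc.simulate_cohort(spec, tmp_path / "c")
        p = sc.read_participant(dirs[0])
        assert set(p.voxels) == {"b0"}
        assert p.trajectory.t.size > 0
        assert p.truth["pid"] == p.pid
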