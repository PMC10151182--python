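import numpy as np
import pytest

from gridtheta import epochs as em
from gridtheta.navio import VoxelSeries

from conftest import make_traj


class TestMovementOnsets:
    def test_short_bout_not_detected(self):
        traj = make_traj([(False, 2.0, 0), (True, 0.8, 0), (False, 2.0, 0)])
        assert len(em.detect_movement_onsets(traj)) == 0

    def test_qualifying_bout_detected(self):
        traj = make_traj([(False, 1.5, 0), (True, 1.2, 0), (False, 1.0, 0)])
        es = em.detect_movement_onsets(traj)
        assert len(es) == 1
        assert es.onsets[0] == pytest.approx(1.5)

    def test_boundary_durations_inclusive(self):
        # exactly 1 s movement after exactly 1 s immobility qualifies
        traj = make_traj([(False, 1.0, 0), (True, 1.0, 0), (False, 1.0, 0)])
        assert len(em.detect_movement_onsets(traj)) == 1

    def test_insufficient_preceding_immobility(self):
        traj = make_traj([(False, 0.5, 0), (True, 2.0, 0), (False, 2.0, 0)])
        assert len(em.detect_movement_onsets(traj)) == 0

    def test_bout_at_recording_start_excluded(self):
        traj = make_traj([(True, 2.0, 0), (False, 2.0, 0)])
        assert len(em.detect_movement_onsets(traj)) == 0

    def test_schedule_fixture_hand_enumeration(self, schedule_traj):
        # pauses at [0,2), [4,6), ..., bouts at [2,4), [6,8), ..., [38,40)
        # all 10 bouts are >=1 s preceded by 2 s immobility -> 10 onsets;
        # full [-3, 3] windows fit only for onsets in [3, 37] -> 8 accepted
        es = em.detect_movement_onsets(schedule_traj)
        assert len(es) == 10
        np.testing.assert_allclose(es.onsets, 2.0 + 4.0 * np.arange(10))
        assert es.n_accepted == 8
        assert not es.accepted[0] and not es.accepted[-1]

    def test_onset_invariant_immobile_before_moving_after(self, schedule_traj):
        es = em.detect_movement_onsets(schedule_traj)
        rate = schedule_traj.sample_rate
        for onset in es.onsets:
            i = int(round(onset * rate))
            assert schedule_traj.moving[i:i + int(rate)].all()
            assert not schedule_traj.moving[i - int(rate):i].any()

    def test_empty_log_gives_empty_set(self):
        traj = make_traj([(False, 1.0, 0)])
        es = em.detect_movement_onsets(traj)
        assert len(es) == 0


class TestStationaryOnsets:
    def test_just_under_two_seconds_not_detected(self):
        traj = make_traj([(True, 2.0, 0), (False, 1.9, 0), (True, 2.0, 0)])
        assert len(em.detect_stationary_onsets(traj)) == 0

    def test_exactly_two_seconds_detected(self):
        traj = make_traj([(True, 2.0, 0), (False, 2.0, 0), (True, 2.0, 0)])
        es = em.detect_stationary_onsets(traj)
        assert len(es) == 1
        assert es.onsets[0] == pytest.approx(2.0)

    def test_schedule_fixture_hand_enumeration(self, schedule_traj):
        # immobile runs [0,2), [4,6), ..., [36,38): all exactly 2 s -> 10
        # onsets at 0, 4, ..., 36; [-2.5, 3.5] windows fit for onsets in
        # [2.5, 36.5] -> onsets 4..36 accepted (9 epochs)
        es = em.detect_stationary_onsets(schedule_traj)
        assert len(es) == 10
        np.testing.assert_allclose(es.onsets, 4.0 * np.arange(10))
        assert es.n_accepted == 9


class TestOverlapExclusion:
    def test_two_second_pause_no_exclusions(self, schedule_traj):
        # stationary [0,1] windows end 1 s into each pause; the next
        # movement [-0.5, 0.5] window starts 1.5 s into the pause
        move = em.detect_movement_onsets(schedule_traj)
        stat = em.detect_stationary_onsets(schedule_traj)
        times = np.arange(0, 40, 1 / 200.0)
        mask = em.exclude_overlap(move, stat, times)
        assert not mask.any()

    def test_overlapping_windows_masked(self):
        # immobility of 2 s followed by movement whose [-0.5, .5] window
        # reaches back into the stationary [0, 1] window when the pause is
        # short enough: craft stationary onset at 0 and movement onset at 1.2
        traj = make_traj([(True, 1.5, 0), (False, 2.0, 0), (True, 1.5, 0),
                          (False, 1.0, 0)])
        # stationary onset at 1.5 (window [1.5, 2.5]); movement onset 3.5
        move = em.detect_movement_onsets(traj, min_still_s=1.0)
        stat = em.detect_stationary_onsets(traj)
        assert len(move) == 1 and len(stat) == 1
        times = np.arange(0, 6, 1 / 200.0)
        # movement analysis window [3.0, 4.0]; stationary [1.5, 2.5]: disjoint
        mask = em.exclude_overlap(move, stat, times)
        assert not mask.any()
        # force overlap with a wider stationary analysis window
        mask = em.exclude_overlap(move, stat, times, stat_window=(0.0, 2.0))
        lo, hi = 3.0, 3.5  # intersection of [3.0, 4.0] and [1.5, 3.5]
        expected = (times >= lo) & (times <= hi)
        np.testing.assert_array_equal(mask, expected)

    def test_short_pause_produces_no_stationary_epoch(self):
        traj = make_traj([(True, 1.5, 0), (False, 1.2, 0), (True, 1.5, 0)])
        stat = em.detect_stationary_onsets(traj)
        assert len(stat) == 0


class TestGeneralizedESD:
    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(0)
        any_reject = 0
        for _ in range(200):
            x = rng.normal(size=50)
            any_reject += em.generalized_esd(x, alpha=0.05).size > 0
        # familywise rejection under the null should be near alpha
        assert any_reject / 200 < 0.12

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        x[17] = 30.0
        assert 17 in em.generalized_esd(x, alpha=0.05)

    def test_alpha_zero_rejects_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        x[3] = 100.0
        assert em.generalized_esd(x, alpha=0.0).size == 0


class TestRejectOutlierEpochs:
    def _setup(self, n_epochs=30, outlier=None, seed=0):
        # 4 s pauses keep the 6 s epoch windows from overlapping each other
        rate = 50.0
        segs = []
        for i in range(n_epochs):
            segs.append((False, 4.0, 0.0))
            segs.append((True, 2.0, 0.0))
        traj = make_traj(segs, rate=rate)
        rng = np.random.default_rng(seed)
        fs = 200.0
        n = int(traj.t[-1] * fs)
        values = rng.normal(size=(2, n))
        es = em.detect_movement_onsets(traj)
        if outlier is not None:
            onset = es.onsets[outlier]
            i0 = int((onset - 3.0) * fs)
            values[:, max(i0, 0):i0 + int(6 * fs)] *= 10.0
        series = VoxelSeries(fs, 0.0, values, block_id="b0")
        return es, series

    def test_planted_variance_outlier_rejected(self):
        es, series = self._setup(outlier=5)
        out = em.reject_outlier_epochs(es, series, alpha=0.05)
        # outlier index 5 among accepted epochs must be rejected
        assert not out.accepted[5]
        assert out.n_accepted >= len(es) - 3

    def test_null_epochs_mostly_accepted(self):
        es, series = self._setup()
        out = em.reject_outlier_epochs(es, series, alpha=0.05)
        assert out.n_accepted >= es.n_accepted - 2

    def test_alpha_zero_keeps_all(self):
        es, series = self._setup(outlier=3)
        out = em.reject_outlier_epochs(es, series, alpha=0.0)
        np.testing.assert_array_equal(out.accepted, es.accepted)

    def test_fewer_than_three_epochs_all_accepted(self, caplog):
        traj = make_traj([(False, 4.0, 0), (True, 2.0, 0), (False, 2.0, 0)])
        es = em.detect_movement_onsets(traj)
        series = VoxelSeries(200.0, 0.0, np.random.default_rng(0).normal(size=(1, 1600)))
        import logging
        with caplog.at_level(logging.WARNING):
            out = em.reject_outlier_epochs(es, series)
        assert out.accepted.all()
        assert "outlier test skipped" in caplog.text


class TestEpochIO:
    def test_hdf5_round_trip(self, tmp_path, schedule_traj):
        move = em.detect_movement_onsets(schedule_traj)
        stat = em.detect_stationary_onsets(schedule_traj)
        path = tmp_path / "epochs.h5"
        em.save_epochs([move, stat], path)
        back = em.load_epochs(path)
        assert back[0].kind == "movement_onset"
        np.testing.assert_allclose(back[0].onsets, move.onsets)
        np.testing.assert_array_equal(back[1].accepted, stat.accepted)
        assert back[1].window == stat.window
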