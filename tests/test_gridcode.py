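import numpy as np
import pytest

from gridtheta import circstat, gridcode
from gridtheta import epochs as em
from gridtheta.errors import InvalidArgumentError, OrientationUndefinedError
from gridtheta.spectral import BandPowerSeries

from conftest import make_traj


def _dense_theta(n=36000):
    return np.linspace(0.0, 360.0, n, endpoint=False)


class TestEstimateOrientation:
    def test_exact_recovery(self):
        th = _dense_theta()
        power = np.cos(np.deg2rad(6 * (th - 20.0)))
        phi, (bc, bs) = gridcode.estimate_orientation(power, th, 6)
        assert phi == pytest.approx(20.0, abs=1e-6)
        assert np.hypot(bc, bs) == pytest.approx(1.0, rel=1e-9)

    def test_rotation_equivariance(self):
        th = _dense_theta(3600)
        power = np.cos(np.deg2rad(6 * (th - 20.0)))
        phi0, _ = gridcode.estimate_orientation(power, th, 6)
        phi1, _ = gridcode.estimate_orientation(power, th + 7.0, 6)
        assert phi1 == pytest.approx(float(circstat.fold(phi0 + 7.0, 6)), abs=1e-6)

    def test_noisy_monte_carlo_recovery(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            th = rng.uniform(0, 360, size=10_000)
            power = np.cos(np.deg2rad(6 * (th - 20.0))) + rng.normal(0, 0.5, th.size)
            phi, _ = gridcode.estimate_orientation(power, th, 6)
            err = abs(circstat.circ_dev_nfold(phi, 20.0, 6))
            hits += err <= 2.0
        assert hits >= 38  # >= 95% of seeds

    def test_constant_direction_undefined(self):
        with pytest.raises(OrientationUndefinedError):
            gridcode.estimate_orientation(np.ones(10), np.full(10, 33.0), 6)


class TestRegressModulation:
    def test_exact_slope(self):
        th = _dense_theta(3600)
        power = 2.0 + 3.0 * np.cos(np.deg2rad(6 * (th - 11.0)))
        assert gridcode.regress_modulation(power, th, 11.0, 6) == pytest.approx(3.0)

    def test_half_period_misestimate_flips_sign(self):
        th = _dense_theta(3600)
        power = 2.0 + 3.0 * np.cos(np.deg2rad(6 * (th - 11.0)))
        assert gridcode.regress_modulation(power, th, 41.0, 6) == pytest.approx(-3.0)

    def test_direction_independent_power_near_zero(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 360, 5000)
        power = rng.normal(size=5000)
        beta = gridcode.regress_modulation(power, th, 10.0, 6)
        se = 1.0 / np.sqrt(5000 / 2)  # sd(power)/sqrt(n * var(cos))
        assert abs(beta) < 3 * se


class TestSplitAlternate:
    @pytest.mark.parametrize("n,sizes", [(5, (3, 2)), (2, (1, 1)), (7, (4, 3))])
    def test_sizes(self, n, sizes):
        a, b = gridcode.split_alternate(np.arange(n))
        assert (len(a), len(b)) == sizes
        assert set(a) | set(b) == set(range(n))

    def test_deterministic(self):
        a1, b1 = gridcode.split_alternate([3, 1, 2])
        a2, b2 = gridcode.split_alternate([1, 2, 3])
        np.testing.assert_array_equal(a1, a2)

    def test_single_epoch_raises(self):
        with pytest.raises(InvalidArgumentError):
            gridcode.split_alternate([0])


class TestMovementSamples:
    def _power(self, traj, fs=200.0):
        n = int(np.floor((traj.t[-1] - traj.t[0]) * fs)) + 1
        vals = np.zeros((1, n))
        return BandPowerSeries((4, 10), fs, traj.t[0], vals,
                               np.zeros(1), np.ones(1), block_id="b0")

    def test_sample_count_for_bout(self):
        # 1.5 s bout at 200 Hz -> 300 samples from that epoch
        traj = make_traj([(False, 2.0, 0.0), (True, 1.5, 45.0), (False, 2.0, 0.0)],
                         rate=50.0)
        es = em.detect_movement_onsets(traj)
        es.accepted[:] = True  # window truncation is irrelevant here
        bs = gridcode.movement_samples(es, traj, self._power(traj))
        assert bs.power.shape[0] == 300
        assert np.all(bs.direction_deg == 45.0)

    def test_pre_onset_samples_never_included(self):
        traj = make_traj([(False, 2.0, 10.0), (True, 2.0, 90.0), (False, 1.0, 0.0)],
                         rate=50.0)
        es = em.detect_movement_onsets(traj)
        es.accepted[:] = True
        bs = gridcode.movement_samples(es, traj, self._power(traj))
        assert np.all(bs.direction_deg == 90.0)

    def test_totals_match_hand_count_across_epochs(self):
        segs = []
        bouts = [1.5, 2.0, 1.0, 2.5, 1.2]
        for b, h in zip(bouts, (0, 60, 120, 180, 240)):
            segs.append((False, 2.0, 0.0))
            segs.append((True, b, float(h)))
        segs.append((False, 2.0, 0.0))
        traj = make_traj(segs, rate=50.0)
        es = em.detect_movement_onsets(traj)
        es.accepted[:] = True
        bs = gridcode.movement_samples(es, traj, self._power(traj))
        assert bs.power.shape[0] == int(sum(b * 200 for b in bouts))
        assert len(np.unique(bs.epoch_index)) == 5


class TestAlignedContrast:
    def test_closed_form_four_over_pi(self):
        # mean of cos over the aligned sector minus the misaligned sector
        # equals 4/pi; verified against dense numeric integration
        th = _dense_theta(720_000)
        power = np.cos(np.deg2rad(6 * (th - 23.0)))
        diff, frac = gridcode.aligned_contrast(power, th, 23.0, 6, 15.0)
        assert diff == pytest.approx(4 / np.pi, abs=1e-3)
        # independent numeric oracle on the folded angle x = 6*theta
        x = np.linspace(-np.pi, np.pi, 2_000_001)
        numeric = (np.mean(np.cos(x[np.abs(x) <= np.pi / 2]))
                   - np.mean(np.cos(x[np.abs(x) > np.pi / 2])))
        assert diff == pytest.approx(numeric, abs=1e-3)

    def test_uniform_directions_half_aligned(self):
        th = _dense_theta(100_000)
        _, frac = gridcode.aligned_contrast(np.cos(np.deg2rad(6 * th)), th, 0.0, 6, 15.0)
        assert frac == pytest.approx(0.5, abs=1e-3)

    def test_direction_independent_power_no_contrast(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 360, 20_000)
        diff, _ = gridcode.aligned_contrast(rng.normal(size=20_000), th, 10.0, 6, 15.0)
        assert abs(diff) < 0.05

    def test_invalid_width(self):
        with pytest.raises(InvalidArgumentError):
            gridcode.aligned_contrast(np.ones(10), _dense_theta(10), 0.0, 6, 40.0)


class TestCrossval:
    def _block(self, seed, gain=0.0, phi=20.0, n_epochs=20, per_epoch=60):
        rng = np.random.default_rng(seed)
        dirs, power, ep = [], [], []
        for e in range(n_epochs):
            th = rng.uniform(0, 360)
            d = np.full(per_epoch, th)
            p = gain * np.cos(np.deg2rad(6 * (d - phi))) + rng.normal(0, 1, per_epoch)
            dirs.append(d)
            power.append(p)
            ep.append(np.full(per_epoch, e))
        return gridcode.BlockSamples("b0", np.concatenate(power)[:, None],
                                     np.concatenate(dirs), np.concatenate(ep),
                                     np.ones(1))

    def test_null_crossval_unbiased(self):
        betas = [gridcode.crossval_grid([self._block(s)], 6)[0][0]
                 for s in range(60)]
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(betas.size)
        assert abs(betas.mean()) < 3 * se + 1e-3

    def test_planted_modulation_recovered(self):
        betas = np.array([gridcode.crossval_grid(
            [self._block(s, gain=1.0, n_epochs=40)], 6)[0][0] for s in range(20)])
        assert betas.mean() == pytest.approx(1.0, abs=0.15)

    def test_orientation_stored_per_fold(self):
        _, fits = gridcode.crossval_grid([self._block(0, gain=2.0, n_epochs=40)], 6)
        assert {f.fold for f in fits} == {"A", "B"}
        for f in fits:
            assert 0 <= f.orientation_deg < 60.0

    def test_rotation_equivariance_of_pipeline(self):
        bs = self._block(1, gain=1.5, n_epochs=40)
        beta0, fits0 = gridcode.crossval_grid([bs], 6)
        rotated = gridcode.BlockSamples(bs.block_id, bs.power,
                                        (bs.direction_deg + 13.0) % 360.0,
                                        bs.epoch_index, bs.envelope_sd)
        beta1, fits1 = gridcode.crossval_grid([rotated], 6)
        assert beta1[0] == pytest.approx(beta0[0], abs=1e-9)
        for f0, f1 in zip(fits0, fits1):
            assert f1.orientation_deg == pytest.approx(
                float(circstat.fold(f0.orientation_deg + 13.0, 6)), abs=1e-6)


class TestControlAnalyses:
    def test_table_shape_and_keys(self):
        blocks = {name: [TestCrossval()._block(0, gain=0.5 if name == "theta" else 0.0,
                                               n_epochs=20)]
                  for name in ("delta", "theta")}
        df = gridcode.control_analyses(blocks, symmetries=(4, 6))
        assert set(df["band"]) == {"delta", "theta"}
        assert set(df["symmetry"]) == {4, 6}
        assert len(df) == 4
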