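import numpy as np
import pytest
from scipy import stats

from ecgssm.augment import (EpochMixReport, MixConfig, ParticipationSchedule,
                            apply_epoch, cutmix_pair, mixup_pair,
                            participation_fraction, sample_lambda)


class TestParticipationFraction:
    ramp = ParticipationSchedule()

    @pytest.mark.parametrize("epoch,expected", [
        (1, 0.2), (2, 0.4), (3, 0.6), (4, 0.8), (5, 0.8), (100, 0.8)])
    def test_default_ramp(self, epoch, expected):
        assert participation_fraction(epoch, self.ramp) == pytest.approx(
            expected)

    def test_cycle_pattern_indexes_by_epoch(self):
        sched = ParticipationSchedule(mode="cycle",
                                      cycle_pattern=(0.0, 0.6, 0.8, 0.0))
        assert participation_fraction(2, sched) == 0.6
        assert [participation_fraction(e, sched) for e in (1, 3, 4)] == \
            [0.0, 0.8, 0.0]

    def test_cycle_repeats_last_entry(self):
        sched = ParticipationSchedule(mode="cycle",
                                      cycle_pattern=(0.8, 0.8, 0.8))
        assert participation_fraction(50, sched) == 0.8

    def test_constant_mode(self):
        sched = ParticipationSchedule(mode="constant", cap=1.0)
        assert participation_fraction(1, sched) == 1.0

    def test_epochs_are_one_based(self):
        with pytest.raises(ValueError):
            participation_fraction(0, self.ramp)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ParticipationSchedule(ramp_step=1.5)
        with pytest.raises(ValueError):
            ParticipationSchedule(cap=0.1, ramp_step=0.2)


class TestSampleLambda:
    def test_beta_10_10_mean_is_half(self, rng):
        draws = [sample_lambda(MixConfig(), rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_beta_1_1_is_uniform(self, rng):
        draws = [sample_lambda(MixConfig(alpha=1, beta=1), rng)
                 for _ in range(10_000)]
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_all_draws_in_unit_interval(self, rng):
        draws = np.array([sample_lambda(MixConfig(), rng)
                          for _ in range(2000)])
        assert np.all((draws >= 0) & (draws <= 1))

    def test_shapes_must_be_positive(self):
        with pytest.raises(ValueError):
            MixConfig(alpha=0)


class TestMixupPair:
    x_c, x_r = np.array([[2.0, 4.0]]), np.array([[0.0, 0.0]])
    l_c, l_r = np.array([1.0, 0.0]), np.array([0.0, 1.0])

    def test_lambda_one_returns_first_sample(self):
        m = mixup_pair(self.x_c, self.x_r, self.l_c, self.l_r, 1.0)
        assert np.array_equal(m.signal, self.x_c)
        assert np.array_equal(m.label, self.l_c)

    def test_lambda_zero_returns_second_sample(self):
        m = mixup_pair(self.x_c, self.x_r, self.l_c, self.l_r, 0.0)
        assert np.array_equal(m.signal, self.x_r)
        assert np.array_equal(m.label, self.l_r)

    def test_midpoint(self):
        m = mixup_pair(self.x_c, self.x_r, self.l_c, self.l_r, 0.5)
        assert np.array_equal(m.signal, [[1.0, 2.0]])
        assert np.array_equal(m.label, [0.5, 0.5])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixup_pair(self.x_c, np.zeros((1, 3)), self.l_c, self.l_r, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_label_mass_conservation_and_convexity(self, seed):
        rng = np.random.default_rng(seed)
        l_c, l_r = rng.random(26), rng.random(26)
        lam = rng.random()
        m = mixup_pair(rng.normal(size=(12, 64)), rng.normal(size=(12, 64)),
                       l_c, l_r, lam)
        expected_mass = lam * l_c.sum() + (1 - lam) * l_r.sum()
        assert abs(m.label.sum() - expected_mass) < 1e-12
        lo, hi = np.minimum(l_c, l_r), np.maximum(l_c, l_r)
        assert np.all(m.label >= lo - 1e-12)
        assert np.all(m.label <= hi + 1e-12)


class TestCutmixPair:
    def test_segment_length_exact(self, rng):
        x_c, x_r = rng.normal(size=(12, 8192)), rng.normal(size=(12, 8192))
        m = cutmix_pair(x_c, x_r, np.array([1.0, 0]), np.array([0, 1.0]),
                        0.2, start=1000)
        replaced = np.sum(np.any(m.signal != x_c, axis=0))
        assert replaced == 1638                      # round(0.2 * 8192)

    def test_segment_copies_partner_exactly(self, rng):
        x_c, x_r = rng.normal(size=(2, 100)), rng.normal(size=(2, 100))
        m = cutmix_pair(x_c, x_r, np.zeros(2), np.ones(2), 0.3, start=10)
        assert np.array_equal(m.signal[:, 10:40], x_r[:, 10:40])
        assert np.array_equal(m.signal[:, :10], x_c[:, :10])
        assert np.array_equal(m.signal[:, 40:], x_c[:, 40:])
        assert np.allclose(m.label, 0.3)

    def test_tiny_fraction_clips_to_one_sample(self, rng):
        x = rng.normal(size=(2, 1000))
        with pytest.warns(UserWarning, match="clipped"):
            m = cutmix_pair(x, rng.normal(size=(2, 1000)),
                            np.array([1.0, 0]), np.array([0, 1.0]),
                            1e-5, start=0)
        assert np.allclose(m.label, [0.999, 0.001])

    def test_fraction_bounds(self, rng):
        x = rng.normal(size=(1, 10))
        with pytest.raises(ValueError):
            cutmix_pair(x, x, np.zeros(1), np.zeros(1), 1.0)


class TestApplyEpoch:
    def _dataset(self, n, rng, dim=4):
        return [(rng.normal(size=dim), rng.integers(0, 2, 3).astype(float))
                for _ in range(n)]

    def test_epoch2_mixes_exactly_40_of_100(self, rng):
        data = self._dataset(100, rng)
        _, report = apply_epoch(data, 2, ParticipationSchedule(), MixConfig(),
                                rng)
        assert report.n_mixed == 40

    def test_ramp_counts_over_ten_epochs_at_n_1000(self, rng):
        data = self._dataset(1000, rng, dim=2)
        counts = []
        for epoch in range(1, 11):
            _, report = apply_epoch(data, epoch, ParticipationSchedule(),
                                    MixConfig(), rng)
            counts.append(report.n_mixed)
        assert counts == [200, 400, 600, 800, 800, 800, 800, 800, 800, 800]

    def test_zero_fraction_returns_dataset_unchanged(self, rng):
        data = self._dataset(10, rng)
        sched = ParticipationSchedule(mode="cycle", cycle_pattern=(0.0,))
        out, report = apply_epoch(data, 1, sched, MixConfig(), rng)
        assert report.n_mixed == 0
        for (xa, la), (xb, lb) in zip(out, data):
            assert xa is xb and la is lb

    def test_non_participants_untouched(self, rng):
        data = self._dataset(50, rng)
        out, report = apply_epoch(data, 1, ParticipationSchedule(),
                                  MixConfig(), rng)
        mixed = set(report.participants.tolist())
        for i, ((xo, lo), (xd, ld)) in enumerate(zip(out, data)):
            if i not in mixed:
                assert xo is xd

    def test_deterministic_given_rng_state(self):
        data = self._dataset(30, np.random.default_rng(5))
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            out, report = apply_epoch(data, 3, ParticipationSchedule(),
                                      MixConfig(), rng)
            runs.append((out, report))
        (o1, r1), (o2, r2) = runs
        assert np.array_equal(r1.participants, r2.participants)
        assert np.array_equal(r1.partners, r2.partners)
        assert np.array_equal(r1.lambdas, r2.lambdas)
        for (xa, _), (xb, _) in zip(o1, o2):
            assert np.array_equal(xa, xb)

    def test_participation_is_uniform_across_samples(self):
        """Over 500 epochs at fraction 0.2 on N=50, every sample's
        participation count is consistent with Binomial(500, 0.2)."""
        rng = np.random.default_rng(123)
        data = [(np.zeros(1), np.zeros(1)) for _ in range(50)]
        sched = ParticipationSchedule(mode="constant", cap=0.2)
        counts = np.zeros(50)
        for _ in range(500):
            _, report = apply_epoch(data, 1, sched, MixConfig(), rng)
            np.add.at(counts, report.participants, 1)
        # chi-square against the uniform expectation of 100 each
        assert stats.chisquare(counts).pvalue > 0.001

    def test_cutmix_mode_runs(self, rng):
        data = self._dataset(20, rng, dim=64)
        out, report = apply_epoch(data, 4, ParticipationSchedule(),
                                  MixConfig(), rng, mode="cutmix")
        assert report.n_mixed == 16
        assert isinstance(report, EpochMixReport)

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_epoch([], 1, ParticipationSchedule(), MixConfig(), rng)
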