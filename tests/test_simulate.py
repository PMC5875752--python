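"""Synthetic-data generator: rate draws, latent trajectories, observation models."""

import numpy as np
import pytest

from cirpop.demography import DemographicRates, build_transition_matrix, stable_structure
from cirpop.simulate import (
    DetectionModel,
    ProportionalHarvest,
    RateRanges,
    draw_rates,
    make_dataset,
    observe_post,
    observe_pre,
    observe_tot,
    simulate_study,
    simulate_trajectory,
)


class TestDrawRates:
    def test_degenerate_range_is_point_mass(self):
        ranges = RateRanges(f=(0.9, 0.9), phi1=(0.9, 0.9), phi2=(0.9, 0.9), n1=(1000, 1000))
        rates, n1 = draw_rates(ranges, np.random.default_rng(0))
        assert (rates.f, rates.phi1, rates.phi2, n1) == (0.9, 0.9, 0.9, 1000)

    def test_uniform_mean_and_support(self):
        rng = np.random.default_rng(1)
        ranges = RateRanges()
        draws = np.array([draw_rates(ranges, rng)[0].f for _ in range(10_000)])
        assert np.all((draws >= 0.60) & (draws <= 0.95))
        se = (0.95 - 0.60) / np.sqrt(12 * 10_000)
        assert abs(draws.mean() - 0.775) <= 3 * se

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lower > upper"):
            RateRanges(f=(0.9, 0.8))


class TestTrajectory:
    def test_pure_aging_conserves_total(self):
        # no reproduction, no mortality, no harvest: everyone piles into adults
        rates = DemographicRates(f=0.0, phi1=0.9, phi2=1.0)
        truth = simulate_trajectory(1000, rates, None, 8, np.random.default_rng(0))
        totals = truth.pre_harvest_totals()
        assert np.all(totals == totals[0])
        assert truth.n[-1, 0] == truth.n[-1, 3] == 0  # no calves left
        assert truth.n[-1, 2] + truth.n[-1, 5] == totals[0]  # all adult

    def test_seeded_replay_is_bitwise_identical(self):
        rates = DemographicRates(f=0.8, phi1=0.9, phi2=0.92)
        a = simulate_trajectory(2000, rates, ProportionalHarvest(), 20, np.random.default_rng(5))
        b = simulate_trajectory(2000, rates, ProportionalHarvest(), 20, np.random.default_rng(5))
        np.testing.assert_array_equal(a.n, b.n)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.births, b.births)

    def test_replicate_mean_matches_matrix_projection(self):
        """Zero harvest: the replicate mean at t=5 tracks the 5-step matrix power."""
        rates = DemographicRates(f=0.8, phi1=0.9, phi2=0.92)
        rng = np.random.default_rng(11)
        lam, w = stable_structure(rates)
        x0 = np.rint(w * 2000 / lam).astype(np.int64)
        a = build_transition_matrix(rates)
        expected = np.linalg.matrix_power(a, 5) @ x0
        reps = 500
        finals = np.array(
            [simulate_trajectory(2000, rates, None, 5, rng).n[4] for _ in range(reps)],
            dtype=float,
        )
        se = finals.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(finals.mean(axis=0) - expected) <= 3 * np.maximum(se, 1e-9))

    def test_excess_harvest_truncated_with_warning(self, caplog):
        rates = DemographicRates(f=0.7, phi1=0.9, phi2=0.9)
        policy = lambda n, t: np.full(6, 10**9)  # noqa: E731 - absurd request
        with caplog.at_level("WARNING"):
            truth = simulate_trajectory(1000, rates, policy, 3, np.random.default_rng(0))
        assert "truncated" in caplog.text
        assert np.all(truth.x >= 0)


class TestObservationModels:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth():
        rates = DemographicRates(f=0.8, phi1=0.9, phi2=0.92)
        return simulate_trajectory(
            2500, rates, ProportionalHarvest(), 10, np.random.default_rng(3)
        )

    def test_perfect_detection_reproduces_latent(self, truth):
        rng = np.random.default_rng(0)
        calves, fy = observe_pre(truth, 4, 1.0, 1.0, rng)
        assert calves == truth.births[4] and fy == truth.fy_pool(4)
        c, f, m = observe_post(truth, 4, 1.0, 1.0, 1.0, rng)
        x = truth.x[4]
        assert (c, f, m) == (x[0] + x[3], x[1] + x[2], x[4] + x[5])

    def test_zero_detection_gives_zero_counts(self, truth):
        rng = np.random.default_rng(0)
        assert observe_pre(truth, 2, 0.0, 1.0, rng) == (0, 0)
        assert observe_post(truth, 2, 0.5, 1.0, 0.0, rng)[2] == 0

    def test_pre_fy_mean_tracks_biased_detection(self, truth):
        rng = np.random.default_rng(1)
        p1, rel, n = 0.6, 1.2, 10_000
        pool = truth.fy_pool(4)
        draws = np.array([observe_pre(truth, 4, p1, rel, rng)[1] for _ in range(n)])
        p_eff = p1 * rel
        se = np.sqrt(pool * p_eff * (1 - p_eff) / n)
        assert abs(draws.mean() - pool * p_eff) <= 3 * se

    def test_post_mean_tracks_detection(self, truth):
        rng = np.random.default_rng(2)
        p2, n = 0.7, 10_000
        pool = truth.x[4, 1] + truth.x[4, 2]
        draws = np.array(
            [observe_post(truth, 4, p2, 1.0, 1.0, rng)[1] for _ in range(n)]
        )
        se = np.sqrt(pool * p2 * (1 - p2) / n)
        assert abs(draws.mean() - pool * p2) <= 3 * se

    def test_tot_thinning_biases_counts_low(self, truth):
        rng = np.random.default_rng(3)
        n = 10_000
        total = truth.x[4].sum()
        draws = np.array([observe_tot(truth, 4, 0.7, rng) for _ in range(n)])
        se = np.sqrt(0.7 * total / n)
        assert abs(draws.mean() - 0.7 * total) <= 3 * se

    def test_observed_counts_never_exceed_latent_pools(self, truth):
        rng = np.random.default_rng(4)
        ds = make_dataset(truth, DetectionModel(p1=0.9, p2=0.9), True, rng)
        assert np.all(ds.pre_calves <= truth.births)
        assert np.all(ds.pre_fy <= [truth.fy_pool(t) for t in range(truth.n_years)])
        assert np.all(ds.post_calves <= truth.x[:, 0] + truth.x[:, 3])


class TestMakeDataset:
    def test_tot_flag(self):
        rng = np.random.default_rng(0)
        truth, ds = simulate_study(rng, n_years=6, include_tot=False)
        assert ds.tot is None
        truth2, ds2 = simulate_study(np.random.default_rng(0), n_years=6, include_tot=True)
        assert ds2.tot is not None

    def test_harvest_copied_without_error(self):
        rng = np.random.default_rng(1)
        truth, ds = simulate_study(rng, n_years=6)
        np.testing.assert_array_equal(ds.harvest, truth.harvest)

    def test_seeded_replay_identical(self):
        t1, d1 = simulate_study(np.random.default_rng(9), n_years=8)
        t2, d2 = simulate_study(np.random.default_rng(9), n_years=8)
        np.testing.assert_array_equal(d1.pre_calves, d2.pre_calves)
        np.testing.assert_array_equal(d1.post_males, d2.post_males)
        np.testing.assert_array_equal(d1.tot, d2.tot)

    def test_time_varying_rates_differ_by_year(self):
        truth, _ = simulate_study(np.random.default_rng(2), n_years=10, time_varying=True)
        assert np.std(truth.f_t) > 0 and np.std(truth.phi1_t) > 0
        assert truth.detection.p1_series(10).std() > 0
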