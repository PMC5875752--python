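"""Model specification: exact joint density, priors, summaries, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from cirpop.model import ChangeInRatioModel, MCMCConfig, ModelConfig, ParamLayout
from cirpop.results import check_convergence, split_rhat, summarize_draws
from cirpop.simulate import SurveyDataset


def _binom_logpmf(k, n, p):
    if k < 0 or k > n:
        return -math.inf
    c = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    term_k = k * math.log(p) if k else 0.0
    term_nk = (n - k) * math.log(1 - p) if n - k else 0.0
    return c + term_k + term_nk


def _pois_logpmf(k, lam):
    return k * math.log(lam) - lam - math.lgamma(k + 1)


def _hand_dataset():
    """A tiny 3-year dataset with hand-picked latent states and observations."""
    latent_n = np.array(
        [
            [120, 80, 400, 115, 75, 300],
            [110, 85, 420, 108, 80, 290],
            [105, 90, 430, 100, 82, 280],
        ]
    )
    births = np.array([260, 250, 240])
    harvest = np.array(
        [
            [10, 5, 30, 12, 8, 50],
            [11, 6, 28, 10, 9, 55],
            [9, 4, 33, 11, 7, 48],
        ]
    )
    dataset = SurveyDataset(
        years=[1, 2, 3],
        pre_calves=[180, 170, 160],
        pre_fy=[380, 390, 400],
        post_calves=[150, 140, 135],
        post_females=[310, 320, 330],
        post_males=[200, 195, 190],
        harvest=harvest,
        tot=[900, 910, 880],
    )
    return dataset, latent_n, births


class TestJointLogDensity:
    f, phi1, phi2, p1, p2 = 0.8, 0.9, 0.92, 0.75, 0.65

    def _oracle(self, dataset, latent_n, births, include_tot):
        """Direct summation of binomial/Poisson/multinomial log-pmfs."""
        f, phi1, phi2, p1, p2 = self.f, self.phi1, self.phi2, self.p1, self.p2
        x = latent_n - dataset.harvest
        ll = 0.0
        for t in (1, 2):
            pool = x[t - 1, 1] + x[t - 1, 2]
            ll += _binom_logpmf(births[t], pool, phi2 * f)
            n_f, n_m = latent_n[t, 0], latent_n[t, 3]
            rest = births[t] - n_f - n_m
            ll += (
                math.lgamma(births[t] + 1)
                - math.lgamma(n_f + 1)
                - math.lgamma(n_m + 1)
                - math.lgamma(rest + 1)
                + (n_f + n_m) * math.log(phi1 / 2)
                + rest * math.log(1 - phi1)
            )
            ll += _binom_logpmf(latent_n[t, 1], x[t - 1, 0], phi2)
            ll += _binom_logpmf(latent_n[t, 4], x[t - 1, 3], phi2)
            ll += _binom_logpmf(latent_n[t, 2], x[t - 1, 1] + x[t - 1, 2], phi2)
            ll += _binom_logpmf(latent_n[t, 5], x[t - 1, 4] + x[t - 1, 5], phi2)
        for t in range(3):
            ll += _binom_logpmf(int(dataset.pre_calves[t]), births[t], p1)
            fy = latent_n[t, 1] + latent_n[t, 2] + latent_n[t, 4]
            ll += _binom_logpmf(int(dataset.pre_fy[t]), fy, p1)
            ll += _binom_logpmf(int(dataset.post_calves[t]), x[t, 0] + x[t, 3], p2)
            ll += _binom_logpmf(int(dataset.post_females[t]), x[t, 1] + x[t, 2], p2)
            ll += _binom_logpmf(int(dataset.post_males[t]), x[t, 4] + x[t, 5], p2)
            if include_tot:
                ll += _pois_logpmf(int(dataset.tot[t]), x[t].sum())
        return ll

    @pytest.mark.parametrize("include_tot", [True, False])
    def test_matches_direct_logpmf_summation(self, include_tot):
        dataset, latent_n, births = _hand_dataset()
        model = ChangeInRatioModel(dataset, ModelConfig(include_tot=include_tot))
        got = model.joint_log_density(
            latent_n, births, self.f, self.phi1, self.phi2, self.p1, self.p2
        )
        assert got == pytest.approx(
            self._oracle(dataset, latent_n, births, include_tot), abs=1e-8
        )

    def test_tot_term_is_exactly_the_poisson_sum(self):
        dataset, latent_n, births = _hand_dataset()
        args = (latent_n, births, self.f, self.phi1, self.phi2, self.p1, self.p2)
        with_tot = ChangeInRatioModel(dataset, ModelConfig(include_tot=True))
        without = ChangeInRatioModel(dataset, ModelConfig(include_tot=False))
        x = latent_n - dataset.harvest
        poisson_sum = sum(_pois_logpmf(int(dataset.tot[t]), x[t].sum()) for t in range(3))
        assert with_tot.joint_log_density(*args) - without.joint_log_density(
            *args
        ) == pytest.approx(poisson_sum, abs=1e-8)

    def test_infeasible_latent_states_have_zero_density(self):
        dataset, latent_n, births = _hand_dataset()
        model = ChangeInRatioModel(dataset)
        bad = latent_n.copy()
        bad[1, 0] = 0  # below the harvest off-take
        assert model.joint_log_density(
            bad, births, self.f, self.phi1, self.phi2, self.p1, self.p2
        ) == -np.inf

    def test_finite_at_simulated_truth_with_perfect_detection(self):
        from cirpop.simulate import DetectionModel, simulate_study

        rng = np.random.default_rng(5)
        truth, ds = simulate_study(rng, n_years=6, detection=DetectionModel(p1=1.0, p2=1.0))
        model = ChangeInRatioModel(ds)
        ll = model.joint_log_density(
            truth.n, truth.births, truth.rates.f, truth.rates.phi1, truth.rates.phi2,
            0.999999, 0.999999,
        )
        assert np.isfinite(ll)


class TestMarginalLikelihood:
    def test_numba_and_numpy_engines_agree(self, reference_study):
        _, dataset = reference_study
        model = ChangeInRatioModel(dataset)
        rng = np.random.default_rng(0)
        theta = np.column_stack(
            [
                rng.uniform(0.6, 0.95, 8),
                rng.uniform(0.85, 0.95, 8),
                rng.uniform(0.88, 0.95, 8),
                rng.uniform(0.5, 0.9, 8),
                rng.uniform(0.5, 0.9, 8),
            ]
        )
        series = model.layout.unpack(theta)
        args = (series["f_t"], series["phi1_t"], series["phi2"], series["p1_t"], series["p2_t"])
        a = model._ss.loglik(*args, include_tot=True, engine="numba")
        b = model._ss.loglik(*args, include_tot=True, engine="numpy")
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_out_of_support_parameters_rejected(self, reference_study):
        _, dataset = reference_study
        model = ChangeInRatioModel(dataset)
        theta = np.array([[0.8, 0.9, 1.2, 0.7, 0.7], [0.8, 0.9, 0.92, 0.7, 0.7]])
        lp = model.log_prob(theta)
        assert lp[0] == -np.inf and np.isfinite(lp[1])

    def test_missing_survey_year_only_drops_that_term(self, reference_study):
        _, dataset = reference_study
        import copy

        ds = copy.deepcopy(dataset)
        ds.pre_calves[4] = np.nan
        ds.tot[9] = np.nan
        model = ChangeInRatioModel(ds)
        theta = np.array([[0.8, 0.9, 0.92, 0.7, 0.7]])
        assert np.isfinite(model.log_prob(theta))[0]

    def test_model_needs_three_years_and_matching_tot(self):
        dataset, _, _ = _hand_dataset()
        df = dataset.to_dataframe().iloc[:2]
        from cirpop.io import dataset_from_dataframe

        with pytest.raises(ValueError, match="3 years"):
            ChangeInRatioModel(dataset_from_dataframe(df))
        no_tot = SurveyDataset(
            years=dataset.years, pre_calves=dataset.pre_calves, pre_fy=dataset.pre_fy,
            post_calves=dataset.post_calves, post_females=dataset.post_females,
            post_males=dataset.post_males, harvest=dataset.harvest, tot=None,
        )
        with pytest.raises(ValueError, match="no TOT"):
            ChangeInRatioModel(no_tot, ModelConfig(include_tot=True))


class TestParamLayout:
    def test_dimensions_by_structure(self):
        assert ParamLayout(ModelConfig(include_tot=False), 20).ndim == 5
        assert (
            ParamLayout(
                ModelConfig(include_tot=False, detection_structure="time_varying"), 20
            ).ndim
            == 3 + 40
        )
        assert (
            ParamLayout(
                ModelConfig(include_tot=False, rate_structure="random_year_effects"), 20
            ).ndim
            == 2 * (2 + 20) + 1 + 2
        )

    def test_random_effects_unpack_uses_logit_scale(self):
        layout = ParamLayout(
            ModelConfig(include_tot=False, rate_structure="random_year_effects"), 4
        )
        theta = np.zeros((1, layout.ndim))
        theta[0, layout.slices["alpha_f"]] = 0.0  # expit(0) = 0.5
        theta[0, layout.slices["phi2"]] = 0.9
        theta[0, layout.slices["p1"]] = 0.7
        theta[0, layout.slices["p2"]] = 0.7
        theta[0, layout.slices["alpha_phi1"]] = 2.0
        series = layout.unpack(theta)
        np.testing.assert_allclose(series["f_t"], 0.5)
        np.testing.assert_allclose(series["phi1_t"], 1 / (1 + np.exp(-2.0)))


class TestSummaries:
    def test_constant_chain_summary(self):
        draws = {"v": np.full((2, 200), 3.5)}
        s = summarize_draws(draws)
        assert s.loc["v", "mean"] == 3.5
        assert s.loc["v", "q2.5"] == s.loc["v", "q97.5"] == 3.5

    def test_normal_chain_matches_sample_quantiles(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 5000))
        s = summarize_draws({"z": x})
        assert s.loc["z", "mean"] == pytest.approx(x.mean())
        assert s.loc["z", "q2.5"] == pytest.approx(np.percentile(x, 2.5))
        assert s.loc["z", "q97.5"] == pytest.approx(np.percentile(x, 97.5))

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning, match="retained draws"):
            summarize_draws({"v": np.ones((2, 10))}, rhat=False)


def _split_rhat_oracle(x):
    """Textbook split-R-hat: split chains in half, between/within variance ratio."""
    c, n = x.shape
    half = n // 2
    sub = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = sub.shape
    w = sub.var(axis=1, ddof=1).mean()
    b = n2 * sub.mean(axis=1).var(ddof=1)
    var_plus = (n2 - 1) / n2 * w + b / n2
    return math.sqrt(var_plus / w)


class TestConvergenceDiagnostics:
    def test_identical_chains_give_rhat_near_one(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(500)
        x = np.vstack([row, row])
        assert split_rhat(x) == pytest.approx(1.0, abs=5e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.standard_normal(300), rng.standard_normal(300) + 5.0])
        table = check_convergence({"v": x}, threshold=1.05)
        assert table.loc["v", "rhat"] > 2.0 and bool(table.loc["v", "flagged"])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 400)) + rng.standard_normal((4, 1)) * 0.3
        assert split_rhat(x) == pytest.approx(_split_rhat_oracle(x), abs=1e-6)

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValueError, match="chains"):
            check_convergence({"v": np.ones((1, 100))})


class TestFitDeterminism:
    def test_same_seed_same_summary(self):
        from cirpop.simulate import simulate_study

        rng = np.random.default_rng(12)
        _, ds = simulate_study(rng, n_years=6)
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burnin=150, thin=2, n_walkers=12)
        model = ChangeInRatioModel(ds)
        s1 = model.fit(cfg, seed=99).summary()
        s2 = model.fit(cfg, seed=99).summary()
        pd.testing.assert_frame_equal(s1, s2)

    def test_random_effects_variant_fits(self):
        """The year-random-effects / time-varying-detection variant runs end to end."""
        from cirpop.simulate import simulate_study

        rng = np.random.default_rng(13)
        truth, ds = simulate_study(rng, n_years=8, time_varying=True)
        config = ModelConfig(
            rate_structure="random_year_effects", detection_structure="time_varying"
        )
        cfg = MCMCConfig(n_chains=1, n_iter=600, n_burnin=300, thin=3, n_walkers=None)
        res = ChangeInRatioModel(ds, config).fit(cfg, seed=5)
        s = res.summary(include_latent=False)
        for name in ("f", "phi1", "phi2", "alpha_f", "sigma_f", "p1[1]", "p2[8]"):
            assert name in s.index
        assert np.isfinite(s["mean"]).all()
        # the across-year mean rates should land in a plausible neighbourhood
        assert abs(s.loc["f", "mean"] - truth.f_t.mean()) < 0.2
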