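import numpy as np
import pytest

import modedif as md
import modedif.irt as irt
from modedif.bayes import McmcSchedule, split_rhat


class TestRobustZ:
    def test_zero_median(self):
        assert md.robust_z([-2, -1, 0, 1, 2]) == 0.0

    def test_hand_value(self):
        # med 2, type-7 IQR 2 -> 2 / (0.74 * 2)
        assert md.robust_z([0, 1, 2, 3, 4]) == pytest.approx(1.3514, abs=1e-4)

    def test_normal_draws_recover_mu_over_sigma(self):
        rng = np.random.default_rng(1)
        mu, sigma = 1.3, 0.6
        d = rng.normal(mu, sigma, 10**6)
        assert md.robust_z(d) == pytest.approx(mu / sigma, rel=0.02)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            md.robust_z([0.1, 0.2, 0.3])

    def test_degenerate_posterior_warns(self):
        with pytest.warns(UserWarning, match="IQR"):
            assert md.robust_z([1.0, 1.0, 1.0, 1.0]) == np.inf
        with pytest.warns(UserWarning, match="IQR"):
            assert md.robust_z([-1.0, -1.0, -1.0, -1.0]) == -np.inf

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.4, 0.2, 501)
        assert md.robust_z(d) == md.robust_z(rng.permutation(d))


class TestCredibleInterval:
    def test_interval_covering_zero_gives_zero_delta(self):
        d = np.linspace(-0.1, 0.3, 400)
        lo, hi, delta = md.credible_interval(d)
        assert lo < 0 < hi and delta == 0.0

    def test_positive_interval_delta_is_lower_bound(self):
        d = np.linspace(0.2, 0.5, 400)
        lo, hi, delta = md.credible_interval(d)
        assert lo > 0
        assert delta == pytest.approx(lo)  # min distance from zero = lower bound

    def test_negative_interval_delta_is_absolute_upper_bound(self):
        _, hi, delta = md.credible_interval(np.linspace(-0.5, -0.2, 400))
        assert delta == pytest.approx(abs(hi))

    def test_percentile_oracle_on_uniform_grid(self):
        d = np.linspace(0.0, 1.0, 1000)
        lo, hi, _ = md.credible_interval(d)
        assert lo == pytest.approx(0.025, abs=1e-9)
        assert hi == pytest.approx(0.975, abs=1e-9)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            md.credible_interval(np.ones(39))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 0.1, 777)
        assert md.credible_interval(d) == md.credible_interval(rng.permutation(d))


class TestFlagDif:
    def test_cutoffs(self):
        flag_rz, flag_cri = md.flag_dif(
            [1.96, -2.5, 0.0, 2.0], [0.0, 0.0, 0.0001, 0.0]
        )
        assert flag_rz.tolist() == [False, True, False, True]  # strict at 1.96
        assert flag_cri.tolist() == [False, False, True, False]


class TestSplitRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(4)
        r = split_rhat(rng.standard_normal((3, 400, 2)))
        assert np.all(r < 1.05)

    def test_divergent_chain_detected(self):
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((2, 400))
        draws[1] += 5.0
        assert split_rhat(draws) > 2.0

    def test_within_chain_drift_detected(self):
        draws = np.linspace(0, 5, 400)[None, :].repeat(3, axis=0)
        assert split_rhat(draws) > 1.2


class TestSampler:
    def test_matches_dense_posterior_on_single_item(self):
        """Posterior mean/SD of one item's difficulty vs 2-D grid integration."""
        rng = np.random.default_rng(7)
        n = 120
        th = rng.standard_normal(n)
        a_t, b_t = 1.2, 0.4
        p = md.response_prob(th, a_t, b_t)
        y = (rng.random(n) < p).astype(np.uint8)[:, None]
        # dense numerical posterior over (log alpha, beta)
        lam = np.linspace(-2.0, 2.0, 401)
        bet = np.linspace(-3.0, 3.0, 601)
        z = irt.D * np.exp(lam)[:, None, None] * (th[None, None, :] - bet[None, :, None])
        ll = (y.T[None, None, 0] * z - np.logaddexp(0, z)).sum(-1)
        lp = ll - lam[:, None] ** 2 / (2 * 0.5) - bet[None, :] ** 2 / (2 * 2.0)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        wb = w.sum(axis=0)
        mean_b = (wb * bet).sum()
        sd_b = np.sqrt((wb * (bet - mean_b) ** 2).sum())

        pp = md.ResponseMatrix(values=y, mode="PP")
        cat = md.ResponseMatrix(values=y.copy(), mode="CAT")
        draws = md.estimate_mode_betas(
            pp, cat, np.r_[th, th], schedule=McmcSchedule(3, 1000, 1500), seed=1
        )
        assert draws.beta_pp.mean() == pytest.approx(mean_b, rel=0.02, abs=0.02)
        assert draws.beta_pp.std() == pytest.approx(sd_b, rel=0.02)

    def test_item_without_cat_data_keeps_prior(self, small_mode_data):
        d = small_mode_data
        cat = d["cat"]
        mask = cat.mask.copy()
        mask[:, 3] = False  # item 3 never administered by CAT
        cat_sparse = md.ResponseMatrix(values=cat.values, mask=mask, mode="CAT")
        draws = md.estimate_mode_betas(
            d["pp"], cat_sparse, d["theta_true"],
            schedule=McmcSchedule(2, 400, 600), seed=2, min_usage=50,
        )
        assert draws.usage[3] == 0 and draws.low_usage[3]
        # posterior == prior: SD sqrt(2), mean ~ 0
        assert draws.beta_cat[:, 3].std() == pytest.approx(np.sqrt(2.0), rel=0.15)
        assert abs(draws.beta_cat[:, 3].mean()) < 0.4

    def test_null_and_signal_recovery(self, small_mode_data):
        """No-DIF items recover a ~zero difference; a +0.63 shift is seen."""
        d = small_mode_data
        sched = McmcSchedule(3, 1000, 500)
        pooled = md.estimate_pooled_theta(d["pp"], d["cat"], schedule=sched, seed=3)
        assert np.all(pooled.rhat_beta < 1.1)
        # pooled abilities recover the generating traits
        r = np.corrcoef(pooled.theta_point, d["theta_true"])[0, 1]
        assert r >= 0.9
        draws = md.estimate_mode_betas(
            d["pp"], d["cat"], pooled.theta_point, schedule=sched, seed=4
        )
        diff_mean = draws.diff_draws().mean(axis=0)
        null_items = np.arange(draws.n_items) != d["dif_item"]
        assert np.all(np.abs(diff_mean[null_items]) < 0.35)
        assert 0.3 <= diff_mean[d["dif_item"]] <= 1.0

    def test_delta_cri_consistent_with_posterior_mass(self, small_mode_data):
        d = small_mode_data
        sched = McmcSchedule(2, 300, 300)
        draws = md.estimate_mode_betas(
            d["pp"], d["cat"], d["theta_true"], schedule=sched, seed=5
        )
        diff = draws.diff_draws()
        for j in range(draws.n_items):
            lo, hi, delta = md.credible_interval(diff[:, j])
            if delta > 0:
                sign = np.sign(lo + hi)
                assert np.mean(np.sign(diff[:, j]) != sign) < 0.05

    def test_duplicate_persons_get_equivalent_abilities(self, small_mode_data):
        d = small_mode_data
        pp = d["pp"]
        values = np.vstack([pp.values, pp.values[:1]])  # person 0 duplicated
        pp_dup = md.ResponseMatrix(values=values, mode="PP")
        pooled = md.estimate_pooled_theta(
            pp_dup, d["cat"], schedule=McmcSchedule(2, 400, 800), seed=6
        )
        # identical data -> identical posterior; the MC estimates agree
        assert pooled.theta_point[0] == pytest.approx(pooled.theta_point[-1], abs=0.12)

    def test_person_with_no_responses_excluded(self, small_mode_data):
        d = small_mode_data
        cat = d["cat"]
        mask = cat.mask.copy()
        mask[0, :] = False
        cat2 = md.ResponseMatrix(values=cat.values, mask=mask, mode="CAT")
        with pytest.warns(UserWarning, match="no observed responses"):
            pooled = md.estimate_pooled_theta(
                d["pp"], cat2, schedule=McmcSchedule(1, 50, 50), seed=7
            )
        assert np.isnan(pooled.theta_point[d["pp"].n_persons])
        assert np.isfinite(pooled.theta_point[0])


class TestAnalyzeDif:
    def test_flags_injected_item_and_reports_usage(self, small_mode_data):
        d = small_mode_data
        res = md.analyze_dif(
            d["pp"], d["cat"], schedule=McmcSchedule(2, 300, 250), seed=8
        )
        assert res.rz.shape == (20,)
        frame = res.to_frame()
        assert list(frame["item"]) == list(range(1, 21))
        assert np.all(res.usage == d["cat"].mask.sum(axis=0))
        # the large injected shift on a fully observed item must be flagged
        assert res.flag_rz[d["dif_item"]] and res.flag_cri[d["dif_item"]]
        # flags follow their statistics
        np.testing.assert_array_equal(res.flag_rz, np.abs(res.rz) > 1.96)
        np.testing.assert_array_equal(res.flag_cri, res.delta_cri != 0)
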