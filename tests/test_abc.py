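"""Rejection, scenario choice, regression adjustment and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import msatabc as m
from msatabc.abc import (
    ReferenceTable,
    RetainedSet,
    bottleneck_ratio,
    build_reference_table,
    convert_to_years,
    estimate_posteriors,
    model_choice,
    pca_preevaluation,
    select_closest,
    weighted_quantile,
)
from msatabc.scenarios import default_priors


def synthetic_table(n_rows=400, n_stats=5, scenarios=(1, 2), seed=0,
                    shift_by_scenario=0.0):
    """A hand-built reference table with Gaussian statistics (no simulation)."""
    rng = np.random.default_rng(seed)
    stat_names = tuple(f"s{i}" for i in range(n_stats))
    scen = np.repeat(scenarios, n_rows // len(scenarios))
    S = rng.normal(size=(len(scen), n_stats))
    S[:, 0] += shift_by_scenario * (scen - np.mean(scenarios))
    params = {sym: rng.uniform(100, 10_000, len(scen)) for sym in m.ALL_SYMBOLS}
    df = pd.DataFrame({"scenario": scen, **params,
                       **{n: S[:, i] for i, n in enumerate(stat_names)}})
    return ReferenceTable(df, stat_names, {"seed": seed})


class TestSelectClosest:
    def test_exact_row_retained_at_distance_zero(self):
        table = synthetic_table()
        obs = table.stats()[7]
        ret = select_closest(table, obs, 0.01)
        assert 7 in ret.indices
        assert ret.distances.min() == 0.0

    def test_fraction_one_keeps_everything(self):
        table = synthetic_table()
        ret = select_closest(table, table.stats()[0], 1.0)
        assert len(ret.indices) == table.n_rows

    def test_zero_mad_statistic_dropped_with_warning(self):
        table = synthetic_table()
        table.df["s0"] = 1.0
        with pytest.warns(UserWarning, match="zero-MAD"):
            ret = select_closest(table, table.stats()[3], 0.05)
        assert "s0" not in ret.kept_stats

    def test_retained_enriched_for_true_scenario(self):
        # statistics shifted by scenario: an observation from scenario 2
        # must be over-represented among the retained rows
        table = synthetic_table(n_rows=2000, shift_by_scenario=3.0, seed=4)
        rng = np.random.default_rng(5)
        obs = rng.normal(size=5)
        obs[0] += 3.0 * (2 - 1.5)
        ret = select_closest(table, obs, 0.05)
        frac2 = (ret.scenario_ids == 2).mean()
        assert frac2 > 0.7  # prior proportion is 0.5


class TestModelChoice:
    def test_pure_retained_set_gives_probability_one(self):
        table = synthetic_table(shift_by_scenario=10.0, seed=1)
        obs = np.zeros(5)
        obs[0] = 10.0 * (2 - 1.5)
        ret = select_closest(table, obs, 0.02)
        assert set(ret.scenario_ids) == {2}
        with pytest.warns(UserWarning, match="absent"):
            probs = model_choice(ret)
        t = probs.table.set_index("scenario")
        assert t.loc[2, "p_direct"] == 1.0
        assert t.loc[2, "p_logistic"] == 1.0

    def test_indistinguishable_scenarios_near_half(self):
        # identical generating process for both scenario labels
        table = synthetic_table(n_rows=2000, shift_by_scenario=0.0, seed=2)
        ret = select_closest(table, np.zeros(5), 0.1)
        probs = model_choice(ret).table.set_index("scenario")
        assert probs["p_direct"].sum() == pytest.approx(1.0, abs=1e-9)
        assert probs["p_logistic"].sum() == pytest.approx(1.0, abs=1e-9)
        assert abs(probs.loc[1, "p_logistic"] - 0.5) < 0.15

    def test_bootstrap_cis_bracket_estimate(self):
        table = synthetic_table(n_rows=1000, shift_by_scenario=1.0, seed=3)
        obs = np.zeros(5)
        obs[0] = 0.5
        ret = select_closest(table, obs, 0.1)
        probs = model_choice(ret, n_bootstrap=50,
                             rng=np.random.default_rng(0)).table
        assert ((probs["ci_low"] <= probs["p_logistic"] + 0.1)
                & (probs["p_logistic"] - 0.1 <= probs["ci_high"])).all()

    def test_direct_and_logistic_rank_agree_when_separated(self):
        hits = 0
        for r in range(20):
            table = synthetic_table(n_rows=1000, shift_by_scenario=2.0,
                                    seed=100 + r)
            obs = np.zeros(5)
            obs[0] = 2.0 * (2 - 1.5)
            ret = select_closest(table, obs, 0.05)
            t = model_choice(ret).table.set_index("scenario")
            hits += (t["p_direct"].idxmax() == t["p_logistic"].idxmax())
        assert hits >= 18


class TestEstimatePosteriors:
    def test_point_mass_preserved(self):
        table = synthetic_table(n_rows=300, scenarios=(2,), seed=6)
        table.df["t1"] = 4321.0
        ret = select_closest(table, table.stats()[0], 0.5)
        post = estimate_posteriors(ret, default_priors(), m.SCENARIOS[2])
        assert np.allclose(post.samples["t1"], 4321.0)

    def test_uninformative_statistics_leave_sample_unchanged(self):
        # parameters independent of the statistics: slopes ~ 0 and the
        # adjusted draws stay close to the raw retained draws
        table = synthetic_table(n_rows=3000, scenarios=(2,), seed=7)
        ret = select_closest(table, np.zeros(5), 1.0)
        post = estimate_posteriors(ret, default_priors(), m.SCENARIOS[2])
        raw = ret.params["t1"].to_numpy()
        adj = post.samples["t1"].to_numpy()
        assert stats.ks_2samp(raw, adj).pvalue > 0.001
        assert np.abs(post.slopes.loc["t1"]).max() < 0.1

    def test_full_table_zero_slopes_reproduce_prior(self):
        # fraction = 1 with the regression suppressed must hand back the
        # prior: KS against uniform on the prior interval
        table = synthetic_table(n_rows=3000, scenarios=(2,), seed=8)
        ret = select_closest(table, np.zeros(5), 1.0)
        ret_zero = RetainedSet(
            table=ret.table, indices=ret.indices, distances=ret.distances,
            X=np.zeros_like(ret.X), kept_stats=ret.kept_stats,
            center=ret.center, scale=ret.scale,
        )
        post = estimate_posteriors(ret_zero, default_priors(), m.SCENARIOS[2])
        vals = post.samples["NA"].to_numpy()
        p = stats.kstest(vals, stats.uniform(100, 9900).cdf).pvalue
        assert p > 0.001

    def test_adjustment_respects_prior_bounds(self, rng):
        table = synthetic_table(n_rows=500, scenarios=(2,), seed=9)
        # correlate t1 strongly with s0 so the adjustment moves draws hard
        table.df["t1"] = 100 + 9900 * (
            stats.norm.cdf(table.df["s0"]) * 0.98 + 0.01
        )
        obs = np.array([4.0, 0, 0, 0, 0])  # far outside the cloud
        ret = select_closest(table, obs, 0.2)
        pri = default_priors()
        post = estimate_posteriors(ret, pri, m.SCENARIOS[2])
        for sym in post.samples.columns:
            assert post.samples[sym].between(pri[sym].low, pri[sym].high).all()


class TestUnitsAndRatios:
    def test_generation_to_year_conversion(self):
        assert convert_to_years(6830) == 20_490
        assert convert_to_years(5010) == 15_030
        assert convert_to_years(0) == 0

    def test_bottleneck_ratios_reported_to_one_decimal(self):
        assert bottleneck_ratio(6400, 3380) == 1.9
        assert bottleneck_ratio(14_400, 3240) == 4.4
        assert bottleneck_ratio(16_500, 5480) == 3.0
        assert bottleneck_ratio(5000, 5000) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bottleneck_ratio(100, 0)
        with pytest.raises(ValueError):
            convert_to_years(10, generation_time=0)


class TestWeightedQuantile:
    def test_matches_numpy_for_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2001)
        w = np.ones_like(x)
        got = weighted_quantile(x, [0.05, 0.5, 0.95], w)
        want = np.quantile(x, [0.05, 0.5, 0.95])
        assert np.allclose(got, want, atol=0.01)

    def test_upweighted_point_drags_median(self):
        x = np.array([0.0, 1.0, 2.0])
        w = np.array([1.0, 1.0, 100.0])
        assert weighted_quantile(x, 0.5, w) > 1.5


class TestPCA:
    def test_observed_equal_to_row_has_same_coordinates(self):
        table = synthetic_table(n_rows=300, seed=10)
        obs = table.stats()[11]
        df, _ = pca_preevaluation(table, obs, n_points=300,
                                  rng=np.random.default_rng(1))
        row = df.iloc[:-1][np.isclose(df.iloc[:-1]["PC1"], df.iloc[-1]["PC1"],
                                      atol=1e-9)]
        assert len(row) >= 1

    def test_total_variance_equals_statistic_count(self):
        table = synthetic_table(n_rows=500, n_stats=5, seed=11)
        _, pca = pca_preevaluation(table, table.stats()[0], n_points=500,
                                   rng=np.random.default_rng(2))
        n = 500
        total = pca.explained_variance_.sum() * (n - 1) / n
        assert total == pytest.approx(5.0, rel=1e-6)

    def test_point_mass_divergence_times_separate_clusters(self):
        # two scenario-1 variants fixed at very different split times shift
        # the whole statistic vector coherently (Fst up, diversity down),
        # so the leading PC separates the clusters
        pri = default_priors()
        for sym in ("N1", "N2", "N3", "NA"):
            pri[sym] = m.PriorSpec(sym, 1000, 1000)
        pri["mu_mic"] = m.PriorSpec("mu_mic", 5e-4, 5e-4)
        pri["p_mic"] = m.PriorSpec("p_mic", 0.1, 0.1)
        pri["sni_mic"] = m.PriorSpec("sni_mic", 0, 0)
        frames = []
        for sid, t1 in ((1, 200.0), (2, 9000.0)):
            pri["t1"] = m.PriorSpec("t1", t1, t1)
            pri["db"] = m.PriorSpec("db", t1 / 2, t1 / 2)
            for s in ("N1b", "N2b", "N3b"):
                pri[s] = m.PriorSpec(s, 1000, 1000)
            t = build_reference_table([m.SCENARIOS[1]], pri, 80, 10,
                                      [8, 8, 8], seed=sid)
            t.df["scenario"] = sid
            frames.append(t.df)
        table = ReferenceTable(pd.concat(frames, ignore_index=True),
                               frames and tuple(
                                   c for c in frames[0].columns
                                   if c not in ("scenario",) + m.ALL_SYMBOLS),
                               {})
        obs = table.stats()[0]
        df, _ = pca_preevaluation(table, obs, n_points=160,
                                  rng=np.random.default_rng(3))
        sims = df.iloc[:-1]
        g1 = sims.loc[sims["scenario"] == 1, "PC1"]
        g2 = sims.loc[sims["scenario"] == 2, "PC1"]
        within = max(g1.std(), g2.std())
        assert abs(g1.mean() - g2.mean()) > 3 * within


class TestEndToEndSmall:
    """Simulation-backed checks at deliberately small scale."""

    @pytest.fixture(scope="class")
    def tiny_fit(self):
        rng = np.random.default_rng(44)
        truth = m.WOLF_TRUTH_SCENARIO2
        observed = m.simulate_dataset(m.SCENARIOS[2], truth, 10, [8, 6, 8], rng)
        model = m.DemographicABC(
            observed,
            scenarios=[m.SCENARIOS[1], m.SCENARIOS[2]],
            fraction=0.05,
        )
        return model.fit(n_per_scenario=300, seed=9)

    def test_probabilities_sum_to_one(self, tiny_fit):
        t = tiny_fit.scenario_probabilities
        assert t["p_direct"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t["p_logistic"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_posterior_summary_is_ordered(self, tiny_fit):
        s = tiny_fit.posterior_summary()
        assert (s["q050"] <= s["median"] + 1e-9).all()
        assert (s["median"] <= s["q950"] + 1e-9).all()

    def test_years_conversion_applies_to_time_rows_only(self, tiny_fit):
        g = tiny_fit.posterior_summary()
        y = tiny_fit.posterior_summary(units="years")
        assert y.loc["t1", "median"] == pytest.approx(3 * g.loc["t1", "median"])
        assert y.loc["N1", "median"] == pytest.approx(g.loc["N1", "median"])

    def test_bottleneck_ratio_table(self, tiny_fit):
        if tiny_fit.best_scenario.bottleneck:
            r = tiny_fit.bottleneck_ratios()
            assert len(r) == 3
            assert (r["R"] > 0).all()

    def test_model_check_median_centered_statistic(self, tiny_fit):
        mc = tiny_fit.model_check(n_ppc=150, seed=5)
        assert len(mc) == 21
        assert ((mc["tail_prob"] > 0) & (mc["tail_prob"] <= 1)).all()

    def test_summary_renders(self, tiny_fit):
        text = tiny_fit.summary()
        assert "Scenario posterior probabilities" in text
        assert "t1" in text

    def test_reference_table_round_trip(self, tiny_fit, tmp_path):
        p = tmp_path / "table.csv"
        tiny_fit.reference_table.to_csv(p)
        back = ReferenceTable.from_csv(p)
        assert back.stat_names == tiny_fit.reference_table.stat_names
        pd.testing.assert_frame_equal(back.df, tiny_fit.reference_table.df,
                                      check_exact=False, atol=1e-9)

    def test_same_seed_reproduces_table(self):
        scens = [m.SCENARIOS[1]]
        pri = default_priors()
        t1 = build_reference_table(scens, pri, 20, 5, [4, 3, 3], seed=5)
        t2 = build_reference_table(scens, pri, 20, 5, [4, 3, 3], seed=5)
        pd.testing.assert_frame_equal(t1.df, t2.df)


def test_model_check_flags_grossly_misspecified_observation():
    # posterior concentrated at the truth, but the observation produced by
    # a wildly different history: at least one statistic must come out
    # Bonferroni-significant
    import pandas as pd

    from msatabc.abc import ParameterPosterior, model_check

    truth = m.WOLF_TRUTH_SCENARIO2
    n = 50
    samples = pd.DataFrame({
        sym: np.full(n, truth.as_dict()[sym])
        for sym in m.scenarios.required_symbols(m.SCENARIOS[2])
    })
    post = ParameterPosterior(
        scenario=m.SCENARIOS[2], samples=samples, weights=np.ones(n),
        slopes=pd.DataFrame(), flags={},
    )
    rng = np.random.default_rng(6)
    weird = m.ParameterDraw(N1=20, N2=20, N3=20, NA=20, t1=9000.0,
                            mu_mic=1e-4, p_mic=0.0, sni_mic=0.0)
    obs = m.summary_vector(
        m.simulate_dataset(m.SCENARIOS[1], weird, 20, [10, 8, 9], rng)
    )
    mc = model_check(post, obs, 20, [10, 8, 9], n_ppc=1000, rng=rng)
    assert mc["significant"].sum() >= 1


def test_model_check_tail_probability_centered_on_median():
    # observed exactly at the predictive median must give tail prob ~ 0.5;
    # emulate by checking the empirical formula on symmetric samples
    rng = np.random.default_rng(1)
    sims = rng.normal(size=(999, 1))
    obs = np.median(sims)
    p_low = ((sims <= obs).sum() + 1) / (len(sims) + 1)
    p_high = ((sims >= obs).sum() + 1) / (len(sims) + 1)
    assert 2 * min(p_low, p_high) == pytest.approx(1.0, abs=0.01)
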