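import numpy as np
import pandas as pd
import pytest

from chukarpop.abc_inference import (
    ABCModelChoice,
    ABCParameterEstimator,
    DEFAULT_PRIORS,
    PriorSpec,
    ReferenceTable,
    abc_reject,
    choose_model_direct,
    choose_model_logistic,
    draw_priors,
    estimate_parameters,
    gof_pca,
    make_reference_table,
    pod_validation,
    stat_names,
    summarize,
)
from chukarpop.io_formats import GenotypeMatrix


@pytest.fixture(scope="module")
def small_table():
    """Tiny reference table over the three scenarios (fast)."""
    priors = PriorSpec()
    return make_reference_table(
        [1, 2, 3], priors, 150, seed=7,
        sample_sizes={"thrace": 5, "west": 5, "east": 5, "central": 5},
        n_loci=5,
    )


class TestPriors:
    def test_draws_within_bounds_and_ordered(self):
        spec = PriorSpec()
        df = draw_priors(spec, 500, seed=1)
        for name, (lo, hi) in DEFAULT_PRIORS.items():
            assert df[name].between(lo, hi).all()
        assert (df["t1"] < df["t2"]).all()
        assert (df["t2"] < df["t3"]).all()

    def test_seed_reproducibility(self):
        spec = PriorSpec()
        pd.testing.assert_frame_equal(
            draw_priors(spec, 50, seed=3), draw_priors(spec, 50, seed=3)
        )

    def test_invalid_bounds_rejected(self):
        bad = dict(DEFAULT_PRIORS)
        bad["ra"] = (0.9, 0.1)
        with pytest.raises(ValueError):
            PriorSpec(bad)


class TestSummarize:
    def test_deterministic(self, toy_genotypes):
        s1 = summarize(toy_genotypes)
        s2 = summarize(toy_genotypes)
        np.testing.assert_array_equal(s1, s2)

    def test_identical_groups_zero_differentiation(self):
        rng = np.random.default_rng(0)
        block = rng.integers(10, 14, size=(30, 3, 2))
        block.sort(axis=2)
        alleles = np.concatenate([block, block])
        G = GenotypeMatrix(
            [f"i{k}" for k in range(60)], ["l1", "l2", "l3"],
            alleles, ["p1"] * 30 + ["p2"] * 30,
        )
        names = stat_names(["p1", "p2"])
        s = summarize(G)
        fst = s[names.index("fst_p1_p2")]
        dmu2 = s[names.index("dmu2_p1_p2")]
        assert abs(fst) < 0.05
        assert dmu2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_toy(self):
        """2 groups x 2 individuals x 2 loci: every statistic evaluated
        by hand/plain numpy."""
        alleles = np.array(
            [
                [[10, 12], [20, 20]],
                [[10, 10], [20, 22]],
                [[14, 14], [24, 24]],
                [[14, 14], [24, 24]],
            ]
        )
        G = GenotypeMatrix(
            ["a", "b", "c", "d"], ["l1", "l2"], alleles, ["p1", "p1", "p2", "p2"]
        )
        s = summarize(G)
        names = stat_names(["p1", "p2"])

        # group p1, locus l1: alleles {10,10,10,12} -> Na=2,
        # He = (4/3)(1 - (9/16 + 1/16)) = 0.5, var = ddof1 var of sizes
        var_l1 = np.var([10, 12, 10, 10], ddof=1)
        # locus l2: {20,20,20,22} -> same frequencies
        var_l2 = np.var([20, 20, 20, 22], ddof=1)
        assert s[names.index("na_p1")] == pytest.approx(2.0)
        assert s[names.index("he_p1")] == pytest.approx(0.5)
        assert s[names.index("var_p1")] == pytest.approx((var_l1 + var_l2) / 2)
        # allele-sharing distance: no alleles shared between p1 and p2
        assert s[names.index("das_p1_p2")] == pytest.approx(1.0)
        # (delta mu)^2: ((10.5-14)^2 + (20.5-24)^2)/2
        assert s[names.index("dmu2_p1_p2")] == pytest.approx(12.25)

    def test_undefined_cell_raises(self):
        alleles = np.array([[[0, 0]], [[10, 10]]])
        G = GenotypeMatrix(["a", "b"], ["l1"], alleles, ["p1", "p2"])
        with pytest.raises(ValueError, match="undefined"):
            summarize(G)


class TestRejection:
    def test_observed_row_ranked_first(self, small_table):
        obs = small_table.stats[37]
        idx = abc_reject(obs, small_table, tolerance=0.05)
        assert idx[0] == 37

    def test_full_tolerance_returns_everything(self, small_table):
        idx = abc_reject(small_table.stats[0], small_table, tolerance=1.0)
        assert len(idx) == len(small_table.scenario)

    def test_partial_sort_property(self, small_table):
        obs = small_table.stats[3]
        idx = abc_reject(obs, small_table, tolerance=0.1)
        from chukarpop.abc_inference import _standardize

        S, s_obs, _ = _standardize(small_table.stats, obs)
        d = np.sqrt(((S - s_obs) ** 2).sum(axis=1))
        excluded = np.setdiff1d(np.arange(len(d)), idx)
        assert d[idx].max() <= d[excluded].min() + 1e-12


class TestModelChoice:
    def test_direct_equal_counts_uniform(self):
        ids = np.array([1] * 10 + [2] * 10 + [3] * 10)
        res = choose_model_direct(ids, [1, 2, 3], k=30)
        assert res.direct == {1: pytest.approx(1 / 3), 2: pytest.approx(1 / 3),
                              3: pytest.approx(1 / 3)}

    def test_direct_unanimous(self):
        ids = np.full(50, 2)
        res = choose_model_direct(ids, [1, 2, 3], k=50)
        assert res.direct[2] == 1.0 and res.direct[1] == 0.0

    def test_probabilities_sum_to_one(self, small_table):
        obs = small_table.stats.mean(axis=0)
        idx = abc_reject(obs, small_table, tolerance=0.3)
        res = choose_model_logistic(small_table, idx, obs)
        assert sum(res.logistic.values()) == pytest.approx(1.0, abs=1e-6)
        d = choose_model_direct(small_table.scenario[idx], [1, 2, 3], 1000)
        assert sum(d.direct.values()) == pytest.approx(1.0, abs=1e-6)

    def test_indistinguishable_scenarios_near_half(self):
        """Two scenarios with identical statistic distributions should
        split the posterior, and direct/logistic should agree."""
        rng = np.random.default_rng(5)
        stats = rng.normal(size=(400, 4))
        table = ReferenceTable(
            np.array([1, 2] * 200), np.zeros((400, 0)), stats, [],
            [f"s{i}" for i in range(4)], 0,
        )
        obs = np.zeros(4)
        idx = abc_reject(obs, table, tolerance=0.5)
        res = choose_model_logistic(table, idx, obs)
        assert res.logistic[1] == pytest.approx(0.5, abs=0.15)
        d = choose_model_direct(table.scenario[idx], [1, 2], 1000)
        assert abs(d.direct[1] - res.logistic[1]) < 0.15

    def test_logistic_matches_sklearn_weighted_fit(self, small_table):
        """Posterior at the observed point agrees with an independent
        weighted multinomial fit (sklearn, near-unpenalized)."""
        from sklearn.linear_model import LogisticRegression
        from chukarpop.abc_inference import _epanechnikov, _standardize

        obs = small_table.stats[50]
        idx = abc_reject(obs, small_table, tolerance=0.4)
        res = choose_model_logistic(small_table, idx, obs)

        S, s_obs, _ = _standardize(small_table.stats, obs)
        Sc = S[idx] - s_obs
        w = _epanechnikov(np.sqrt((Sc**2).sum(axis=1)))
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(Sc, small_table.scenario[idx], sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, Sc.shape[1])))[0]
        for cls, p in zip(clf.classes_, probs):
            assert res.logistic[cls] == pytest.approx(p, abs=0.05)

    def test_estimator_interface(self, small_table):
        clf = ABCModelChoice(tolerance=0.2)
        clf.fit(small_table.stats, small_table.scenario)
        proba = clf.predict_proba(small_table.stats[:2])
        assert proba.shape == (2, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert clf.predict(small_table.stats[:1])[0] in (1, 2, 3)

    def test_sklearn_get_set_params(self):
        clf = ABCModelChoice(tolerance=0.2)
        assert clf.get_params()["tolerance"] == 0.2
        clf.set_params(k_direct=10)
        assert clf.k_direct == 10


class TestParameterEstimation:
    def test_adjusted_values_within_prior_bounds(self, small_table):
        priors = PriorSpec()
        obs = small_table.stats[10]
        idx = abc_reject(obs, small_table, tolerance=0.3)
        est = estimate_parameters(small_table, idx, obs, priors)
        for name, (lo, hi) in DEFAULT_PRIORS.items():
            vals = est.posterior_[name]
            assert ((vals >= lo) & (vals <= hi)).all()

    def test_degenerate_statistics_fall_back_to_rejection(self):
        priors = PriorSpec()
        params = draw_priors(priors, 50, seed=2)
        stats = np.ones((50, 3))  # zero variance everywhere
        est = ABCParameterEstimator(priors=priors)
        est.fit(stats, params, np.ones(3))
        assert est.adjusted_ is False
        np.testing.assert_allclose(est.posterior_["ra"], params["ra"])

    def test_cross_check_against_sklearn_weighted_regression(self, small_table):
        """The local-linear adjustment equals a sklearn weighted
        LinearRegression fit on the same design."""
        from sklearn.linear_model import LinearRegression
        from chukarpop.abc_inference import _epanechnikov, _standardize

        priors = PriorSpec()
        obs = small_table.stats[4]
        idx = abc_reject(obs, small_table, tolerance=0.4)
        est = estimate_parameters(small_table, idx, obs, priors)

        stats = small_table.stats[idx]
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        keep = mad > 0
        S = (stats[:, keep] - med[keep]) / mad[keep]
        Sc = S - (obs[keep] - med[keep]) / mad[keep]
        w = _epanechnikov(np.sqrt((Sc**2).sum(axis=1)))
        z = priors.logit("ra", small_table.params[idx][:, 8])
        lr = LinearRegression().fit(Sc, z, sample_weight=w)
        adj = priors.expit("ra", lr.intercept_ + (z - lr.predict(Sc)))
        np.testing.assert_allclose(est.posterior_["ra"], adj, rtol=1e-4, atol=1e-6)


class TestPodValidation:
    def test_identical_scenarios_random_assignment(self):
        """Three identical scenarios: type-I error ~ 2/3."""
        rng = np.random.default_rng(8)
        stats = rng.normal(size=(600, 3))
        table = ReferenceTable(
            np.array([1, 2, 3] * 200), np.zeros((600, 0)), stats, [],
            ["a", "b", "c"], 0,
        )
        hits = []
        for i in range(60):
            obs = rng.normal(size=3)
            idx = abc_reject(obs, table, tolerance=0.2)
            d = choose_model_direct(table.scenario[idx], [1, 2, 3], 1000)
            hits.append(max(d.direct, key=d.direct.get))
        type1 = np.mean([h != 1 for h in hits])
        assert 0.4 < type1 < 0.9

    def test_pod_report_fields(self, small_table):
        priors = PriorSpec()
        report = pod_validation(
            small_table, priors, [1, 2, 3], n_pods=3, seed=4,
            sample_sizes={"thrace": 5, "west": 5, "east": 5, "central": 5},
            n_loci=5, tolerance=0.2, rmae_scenario=2, rmae_params=["ra"],
        )
        assert set(report.type1) == {1, 2, 3}
        for v in report.type1.values():
            assert 0.0 <= v <= 1.0
        assert report.rmae["ra"] >= 0


class TestGofPca:
    def test_observed_from_table_lies_inside_cloud(self, small_table):
        out = gof_pca(small_table, small_table.stats[12])
        coords, obs = out["table"], out["observed"]
        lo = np.quantile(coords, 0.005, axis=0)
        hi = np.quantile(coords, 0.995, axis=0)
        assert np.all(obs[0] >= lo - 1e-9) and np.all(obs[0] <= hi + 1e-9)

    def test_duplicated_row_degenerate_flagged(self):
        stats = np.tile([1.0, 2.0, 3.0], (20, 1))
        table = ReferenceTable(
            np.ones(20, np.int64), np.zeros((20, 0)), stats, [], ["a", "b", "c"], 0
        )
        out = gof_pca(table, stats[0])
        assert out["degenerate"] is True

    def test_projection_deterministic(self, small_table):
        o1 = gof_pca(small_table, small_table.stats[0])
        o2 = gof_pca(small_table, small_table.stats[0])
        np.testing.assert_allclose(o1["table"], o2["table"])


class TestReproducibility:
    def test_reference_table_bit_identical_under_seed(self):
        kw = dict(
            sample_sizes={"thrace": 4, "west": 4, "east": 4, "central": 4},
            n_loci=3,
        )
        t1 = make_reference_table([2], PriorSpec(), 20, seed=13, **kw)
        t2 = make_reference_table([2], PriorSpec(), 20, seed=13, **kw)
        np.testing.assert_array_equal(t1.stats, t2.stats)
        np.testing.assert_array_equal(t1.params, t2.params)

    def test_table_round_trips_through_frame(self, small_table):
        df = small_table.to_frame()
        back = ReferenceTable.from_frame(df)
        np.testing.assert_allclose(back.stats, small_table.stats)
        np.testing.assert_array_equal(back.scenario, small_table.scenario)
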