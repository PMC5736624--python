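import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, fisher_exact, hypergeom

from methstrat.outcome_stats import (
    clopper_pearson,
    cluster_event_summary,
    fisher_exact_rxc,
    kaplan_meier,
    logistic_fit,
    logistic_fit_formula,
    lrt_pvalue,
    odds_ratio_2x2,
)


def _discovery_table():
    return pd.DataFrame(
        {
            "cluster": ["low"] * 15 + ["intermediate"] * 11 + ["high"] * 13,
            "event": [1] + [0] * 14 + [1] * 5 + [0] * 6 + [1] * 8 + [0] * 5,
        }
    )


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        """Intercept of the null model is the sample log-odds ln(14/25)."""
        tab = _discovery_table()
        res = logistic_fit(tab["event"], pd.DataFrame(index=tab.index))
        assert res.coefficients["Intercept"] == pytest.approx(
            np.log(14 / 25), abs=1e-6
        )

    def test_saturated_factor_reproduces_proportions(self):
        tab = _discovery_table()
        res = logistic_fit_formula(tab, "event", ["cluster"], lrt=False)
        co = res.coefficients
        probs = {
            "low": 1 / (1 + np.exp(-co["Intercept"])),
            "intermediate": 1 / (1 + np.exp(-(co["Intercept"] + co["cluster[intermediate]"]))),
            "high": 1 / (1 + np.exp(-(co["Intercept"] + co["cluster[high]"]))),
        }
        assert probs["low"] == pytest.approx(1 / 15, abs=1e-6)
        assert probs["intermediate"] == pytest.approx(5 / 11, abs=1e-6)
        assert probs["high"] == pytest.approx(8 / 13, abs=1e-6)

    def test_saturated_loglik_closed_form(self):
        """Binomial log-likelihood sum k ln(k/n) + (n-k) ln(1-k/n)."""
        expect = sum(
            k * np.log(k / n) + (n - k) * np.log(1 - k / n)
            for k, n in [(1, 15), (5, 11), (8, 13)]
        )
        res = logistic_fit_formula(_discovery_table(), "event", ["cluster"],
                                   lrt=False)
        assert res.loglik == pytest.approx(expect, abs=1e-6)
        assert expect == pytest.approx(-19.915, abs=5e-4)

    def test_missing_covariates_dropped_listwise(self):
        tab = _discovery_table()
        tab.loc[0, "cluster"] = None
        res = logistic_fit_formula(tab, "event", ["cluster"], lrt=False)
        assert res.nobs == 38

    def test_perfect_separation_flagged(self):
        y = [0] * 10 + [1] * 10
        X = pd.DataFrame({"x": np.arange(20.0)})
        res = logistic_fit(y, X)
        assert res.separation_flag

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            logistic_fit([1, 0], pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}))


class TestLrt:
    def test_discovery_cluster_association(self):
        """Three-cluster event counts 1/15, 5/11, 8/13 give p = 0.0039."""
        res = logistic_fit_formula(_discovery_table(), "event", ["cluster"])
        assert res.lrt_p["cluster"] == pytest.approx(0.0039, abs=2e-4)

    def test_identical_models_give_p_one(self):
        res = logistic_fit_formula(_discovery_table(), "event", ["cluster"],
                                   lrt=False)
        dup = logistic_fit_formula(_discovery_table(), "event", ["cluster"],
                                   lrt=False)
        dup.df_model -= 1  # pretend nested with one fewer parameter
        assert lrt_pvalue(res, dup) == pytest.approx(1.0)

    def test_chi2_df2_survival_closed_form(self):
        """chi2_2 upper tail is exp(-x/2); at 11.09 that is ~0.0039."""
        assert chi2.sf(11.09, 2) == pytest.approx(np.exp(-11.09 / 2))
        assert np.exp(-11.09 / 2) == pytest.approx(0.0039, abs=1e-4)

    def test_non_nested_models_rejected(self):
        full = logistic_fit_formula(_discovery_table(), "event", ["cluster"],
                                    lrt=False)
        null = logistic_fit(
            _discovery_table()["event"], pd.DataFrame(index=range(39))
        )
        with pytest.raises(ValueError):
            lrt_pvalue(null, full)  # reversed nesting

    def test_saturated_lrt_equals_binomial_deviance_oracle(self, rng):
        """LRT statistic matches the closed-form deviance on random tables."""
        for _ in range(10):
            counts = rng.integers(1, 9, size=3)
            ns = counts + rng.integers(1, 9, size=3)
            tab = pd.DataFrame(
                {
                    "cluster": np.repeat(["a", "b", "c"], ns),
                    "event": np.concatenate(
                        [[1] * k + [0] * (n - k) for k, n in zip(counts, ns)]
                    ),
                }
            )
            res = logistic_fit_formula(tab, "event", ["cluster"])
            K, N = counts.sum(), ns.sum()

            def ll(k, n):
                out = 0.0
                if 0 < k:
                    out += k * np.log(k / n)
                if k < n:
                    out += (n - k) * np.log(1 - k / n)
                return out

            stat = 2 * (sum(ll(k, n) for k, n in zip(counts, ns)) - ll(K, N))
            assert res.lrt_p["cluster"] == pytest.approx(
                chi2.sf(stat, 2), abs=1e-6
            )


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 22], [9, 3]], 13.2),   # >1 somatic mutation vs <=1
            ([[4, 6], [4, 6]], 1.0),     # symmetric table
            ([[2, 15], [12, 10]], 9.0),  # age >12 months vs <=12
        ],
    )
    def test_cross_product_examples(self, table, expected):
        assert odds_ratio_2x2(table)["or"] == pytest.approx(expected)

    def test_profile_ci_contains_point_estimate(self):
        res = odds_ratio_2x2([[5, 22], [9, 3]])
        assert res["ci_low"] < res["or"] < res["ci_high"]

    def test_profile_ci_inverts_lrt(self):
        """At the profile bound the 1-df LRT p-value is exactly 0.05."""
        from methstrat.outcome_stats import _table_loglik

        res = odds_ratio_2x2([[5, 22], [9, 3]])
        ll_hat = _table_loglik(np.array([[5, 22], [9, 3]]), np.log(res["or"]))
        for bound in (res["ci_low"], res["ci_high"]):
            ll_b = _table_loglik(np.array([[5, 22], [9, 3]]), np.log(bound))
            stat = 2 * (ll_hat - ll_b)
            assert chi2.sf(stat, 1) == pytest.approx(0.05, abs=1e-5)

    def test_wald_method_reported(self):
        res = odds_ratio_2x2([[5, 22], [9, 3]], method="wald")
        assert res["method"] == "wald"
        assert res["ci_low"] < 13.2 < res["ci_high"]

    def test_zero_cell_flagged_infinite_or(self):
        res = odds_ratio_2x2([[5, 5], [5, 0]])
        assert res["zero_cell"]
        assert res["or"] == 0.0 or np.isinf(res["or"]) or res["or"] >= 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2([[1, -1], [2, 3]])


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (8, 13, 32, 86),    # printed 32-86%
            (13, 17, 50, 93),   # printed 50-93%
            (5, 11, 17, 77),
            (4, 11, 11, 69),
            (1, 12, 0, 38),
        ],
    )
    def test_printed_interval_examples(self, k, n, lo, hi):
        from decimal import ROUND_HALF_UP, Decimal

        lower, upper = clopper_pearson(k, n)
        as_pct = lambda x: int(
            Decimal(x * 100).quantize(0, rounding=ROUND_HALF_UP)
        )
        assert (as_pct(lower), as_pct(upper)) == (lo, hi)

    def test_boundary_cases(self):
        assert clopper_pearson(0, 12)[0] == 0.0
        assert clopper_pearson(12, 12)[1] == 1.0

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            k = int(rng.integers(1, n))
            lo, hi = clopper_pearson(k, n)
            assert lo < k / n < hi

    def test_coverage_at_least_nominal(self, rng):
        """Exact intervals cover the truth in >= 95% of binomial draws."""
        p, n, m = 0.3, 15, 10_000
        ks = rng.binomial(n, p, size=m)
        bounds = {k: clopper_pearson(k, n) for k in range(n + 1)}
        covered = sum(bounds[k][0] <= p <= bounds[k][1] for k in ks)
        assert covered / m >= 0.95

    @pytest.mark.parametrize("k,n", [(-1, 5), (6, 5), (0, 0)])
    def test_invalid_inputs(self, k, n):
        with pytest.raises(ValueError):
            clopper_pearson(k, n)


class TestFisherExactRxC:
    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_rxc([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_rxc([[0, 3], [0, 4]]) == 1.0

    def test_modal_2x2_gives_p_one(self):
        assert fisher_exact_rxc([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_matches_scipy_2x2_oracle(self, rng):
        """Freeman-Halton reduces to the classical two-sided 2x2 test."""
        checked = 0
        while checked < 20:
            t = rng.integers(0, 10, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            ours = fisher_exact_rxc(t)
            ref = fisher_exact(t)[1]
            assert ours == pytest.approx(ref, abs=1e-10)
            checked += 1

    def test_matches_direct_hypergeometric_sum(self):
        """Independent 2x2 oracle: sum hypergeometric pmfs <= observed."""
        t = np.array([[3, 7], [6, 2]])
        n = t.sum()
        r1, c1 = t[0].sum(), t[:, 0].sum()
        pmf = lambda a: hypergeom.pmf(a, n, r1, c1)
        p_obs = pmf(t[0, 0])
        total = sum(
            pmf(a)
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if pmf(a) <= p_obs * (1 + 1e-7)
        )
        assert fisher_exact_rxc(t) == pytest.approx(total, abs=1e-10)

    def test_3x3_tissue_by_cluster_plausible(self):
        """A balanced tissue-by-cluster table is far from significant."""
        t = [[5, 7, 4], [8, 9, 7], [2, 3, 2]]
        p = fisher_exact_rxc(t)
        assert 0.5 < p <= 1.0

    def test_monte_carlo_agrees_with_enumeration(self):
        t = [[3, 7], [6, 2]]
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, monte_carlo=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_budget_exceeded_raises(self):
        big = (np.ones((4, 4), dtype=int) * 40).tolist()
        with pytest.raises(RuntimeError, match="Monte|monte"):
            fisher_exact_rxc(big, max_tables=1000)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -2], [3, 4]])


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = kaplan_meier([5, 10, 15], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_four_distinct_events_steps(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        steps = km.set_index("time")["survival"]
        assert steps.loc[0.0] == 1.0
        np.testing.assert_allclose(
            steps.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0]
        )

    def test_censoring_leaves_estimate_unchanged(self):
        km = kaplan_meier([1, 2], [1, 0])
        steps = km.set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(0.5)
        assert steps.loc[2.0] == pytest.approx(0.5)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 20, 30).astype(float)
        km = kaplan_meier(times, np.ones_like(times))
        for t in np.unique(times):
            emp = (times > t).mean()
            got = km.loc[km["time"] == t, "survival"].iloc[0]
            assert got == pytest.approx(emp, abs=1e-10)

    def test_survival_non_increasing(self, rng):
        times = rng.uniform(0, 50, 40)
        events = rng.integers(0, 2, 40)
        km = kaplan_meier(times, events)
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 0])


class TestClusterEventSummary:
    def test_counts_proportions_and_cis(self):
        labels = pd.Series(
            ["low"] * 15 + ["intermediate"] * 11 + ["high"] * 13,
            index=[f"s{i}" for i in range(39)],
        )
        events = pd.Series(
            [1] + [0] * 14 + [1] * 5 + [0] * 6 + [1] * 8 + [0] * 5,
            index=labels.index,
        )
        summary = cluster_event_summary(labels, events)
        assert summary.loc["intermediate", "pct"] == 45
        assert summary.loc["high", "events"] == 8
        assert summary.loc["high", "ci_low_pct"] == 32
        assert summary.loc["high", "ci_high_pct"] == 86
        lo, hi = clopper_pearson(5, 11)
        assert summary.loc["intermediate", "ci_low"] == pytest.approx(lo)
        assert summary.loc["intermediate", "ci_high"] == pytest.approx(hi)
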