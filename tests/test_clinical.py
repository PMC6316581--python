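import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from ptcnmf.clinical import (SeparationError, TwoByTwoTable, build_table2,
                             contingency_test, cox_fit, km_estimate,
                             logistic_fit, logrank_test, odds_ratio_wald)
from ptcnmf.simulate import SyntheticConfig, generate_cohort


class TestOddsRatio:
    def test_published_recurrence_table_values(self):
        """Cluster-3 recurrence 20/153 vs 19/326 gives OR 2.43 (1.26-4.70)."""
        t = TwoByTwoTable.from_events(20, 153, 19, 326)
        res = odds_ratio_wald(t)
        assert round(res.oddsratio, 2) == 2.43
        assert round(res.ci_low, 2) == 1.26
        assert round(res.ci_high, 2) == 4.70

    def test_balanced_table_is_null(self):
        res = odds_ratio_wald(TwoByTwoTable(5, 5, 5, 5))
        assert res.oddsratio == pytest.approx(1.0)

    def test_exposure_flip_reciprocity(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            r1 = odds_ratio_wald(TwoByTwoTable(a, b, c, d))
            r2 = odds_ratio_wald(TwoByTwoTable(c, d, a, b))
            assert r1.oddsratio * r2.oddsratio == pytest.approx(1.0)

    def test_zero_cell_handling(self):
        with pytest.raises(ZeroDivisionError):
            odds_ratio_wald(TwoByTwoTable(0, 5, 3, 7))
        res = odds_ratio_wald(TwoByTwoTable(0, 5, 3, 7),
                              correction="haldane_if_zero")
        assert res.oddsratio == pytest.approx((0.5 * 7.5) / (5.5 * 3.5))


class TestLogistic:
    def test_binary_predictor_matches_cross_product_or(self, rng):
        x = rng.integers(0, 2, 300)
        y = (rng.uniform(size=300) < np.where(x == 1, 0.4, 0.2)).astype(int)
        a = int(((x == 1) & (y == 1)).sum()); b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum()); d = int(((x == 0) & (y == 0)).sum())
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        table_or = odds_ratio_wald(TwoByTwoTable(a, b, c, d)).oddsratio
        assert fit.odds_ratios["x"] == pytest.approx(table_or, abs=1e-8)

    def test_intercept_only_closed_form(self, rng):
        y = rng.permutation(np.r_[np.ones(25), np.zeros(75)])
        x = pd.DataFrame({"x": rng.normal(size=100)})
        # with mean(y)=0.25 and an uninformative covariate the intercept
        # approaches the closed form ln(0.25/0.75)
        fit = logistic_fit(x, y)
        assert fit.params["const"] == pytest.approx(np.log(1 / 3), abs=0.25)

    def test_parameter_recovery_at_n2000(self, rng):
        beta0, beta1 = -2.0, 0.9
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.uniform(size=2000) < p).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        se = np.log(fit.conf_int.loc["x", "ci_high"] / fit.odds_ratios["x"]) / 1.959964
        assert abs(fit.params["x"] - beta1) < 3 * se
        assert abs(fit.params["const"] - beta0) < 3 * 0.1 * 10  # loose intercept bound

    def test_perfect_separation_detected(self):
        x = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            logistic_fit(x, y)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(pd.DataFrame({"x": np.ones(30)}),
                         np.tile([0, 1], 15))


def _fisher_exhaustive(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)
    probs = {x: prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestContingency:
    def test_independent_table_has_zero_statistic(self):
        T = np.outer([10, 20], [3, 7])  # proportional to margins
        chi2, p = contingency_test(T, "chi_square")
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_chi_square_matches_hand_formula(self):
        chi2, _ = contingency_test([[10, 20], [20, 10]], "chi_square")
        # N (ad-bc)^2 / (r1 r2 c1 c2) = 60 * 90000 / 810000
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)

    @pytest.mark.parametrize("table", [(3, 1, 1, 3), (2, 7, 8, 2), (5, 0, 1, 4)])
    def test_fisher_matches_exhaustive_enumeration(self, table):
        a, b, c, d = table
        _, p = contingency_test([[a, b], [c, d]], "fisher_2x2")
        assert p == pytest.approx(_fisher_exhaustive(a, b, c, d), abs=1e-10)

    def test_fisher_three_one_table(self):
        _, p = contingency_test([[3, 1], [1, 3]], "fisher_2x2")
        assert p == pytest.approx(0.4857, abs=1e-4)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curves = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        df = curves["0"]
        s2 = df.loc[df["time"] == 2.0, "survival"].iloc[0]
        assert s2 == pytest.approx((2 / 3) * (1 / 2))

    def test_all_censored_curve_stays_at_one(self):
        curves = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curves["0"]["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, 50)
        curves = km_estimate(t, np.ones(50, dtype=int))
        df = curves["0"]
        for _, row in df[df["time"] > 0].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean(), abs=1e-10)


class TestLogrank:
    def test_identical_groups_are_null(self):
        t = np.r_[np.arange(1, 21), np.arange(1, 21)].astype(float)
        e = np.ones(40, dtype=int)
        g = np.r_[np.zeros(20), np.ones(20)]
        chi2, df, p = logrank_test(t, e, g)
        assert df == 1
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p > 0.99

    def test_strong_separation_is_significant(self, rng):
        t1 = rng.exponential(1.0, 50)
        t2 = 10 * rng.exponential(1.0, 50)
        t = np.r_[t1, t2] + 1e-6
        e = np.ones(100, dtype=int)
        g = np.r_[np.zeros(50), np.ones(50)]
        _, _, p = logrank_test(t, e, g)
        assert p < 0.01

    def test_invariant_to_group_relabeling(self, rng):
        t = rng.exponential(2.0, 60) + 0.01
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = rng.integers(0, 3, 60)
        chi2a, _, _ = logrank_test(t, e, g)
        chi2b, _, _ = logrank_test(t, e, 2 - g)
        assert chi2a == pytest.approx(chi2b, abs=1e-9)


def _cox_partial_loglik(beta, time, event, x):
    """Written-out partial likelihood for one covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_matches_brute_force_grid_on_hand_dataset(self):
        time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(time, event, pd.DataFrame({"x": x}))
        grid = np.linspace(-4, 4, 16001)
        lls = [_cox_partial_loglik(b, time, event, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.params["x"] == pytest.approx(best, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(max(lls), abs=1e-4)

    def test_null_covariate_recovers_unit_hazard(self, rng):
        t = rng.exponential(3.0, 1000) + 1e-3
        e = np.ones(1000, dtype=int)
        x = rng.integers(0, 2, 1000).astype(float)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        se = (np.log(fit.conf_int.loc["x", "ci_high"]) - fit.params["x"]) / 1.959964
        assert abs(fit.params["x"]) < 3 * se

    def test_efron_equals_breslow_without_ties(self, rng):
        t = rng.exponential(2.0, 40) + rng.uniform(0, 1e-3, 40)
        e = rng.integers(0, 2, 40); e[:5] = 1
        X = pd.DataFrame({"x": rng.normal(size=40)})
        f1 = cox_fit(t, e, X, ties="efron")
        f2 = cox_fit(t, e, X, ties="breslow")
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-6)

    def test_hazard_recovery_over_replicates(self):
        """Exponential hazards scaled by exp(beta x) are recovered within
        3 s.e. in nearly all seeded replicates."""
        beta = 0.7
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 400).astype(float)
            t = rng.exponential(1.0 / np.exp(beta * x)) + 1e-6
            e = np.ones(400, dtype=int)
            fit = cox_fit(t, e, pd.DataFrame({"x": x}))
            se = (np.log(fit.conf_int.loc["x", "ci_high"]) - fit.params["x"]) / 1.959964
            hits += abs(fit.params["x"] - beta) < 3 * se
        assert hits >= 19

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestBuildTable2:
    def test_reconstructed_printed_counts_reproduce_or_column(self):
        """Individual-level reconstruction of the printed event/total pairs
        yields the published univariate odds-ratio column."""
        printed = {
            "age_ge55": ((19, 152), (22, 334), 2.03),
            "male": ((13, 119), (24, 331), 1.57),
            "aggressive_variant": ((6, 36), (31, 414), 2.47),
            "extrathyroidal_extension": ((18, 127), (23, 359), 2.41),
            "pt34": ((21, 161), (16, 287), 2.54),
            "pn1": ((26, 199), (15, 287), 2.73),
            "braf_like": ((24, 260), (6, 113), 1.81),
            "high_mutation": ((21, 181), (10, 203), 2.53),
            "nmf3": ((20, 153), (19, 326), 2.43),
        }
        for var, ((ea, na), (eu, nu), expected) in printed.items():
            res = odds_ratio_wald(TwoByTwoTable.from_events(ea, na, eu, nu))
            assert round(res.oddsratio, 2) == expected, var

    def test_null_cohort_odds_ratios_near_one(self):
        rng = np.random.default_rng(99)
        n = 500
        clinical = pd.DataFrame({
            "age": rng.integers(20, 80, n),
            "sex": rng.choice(["Female", "Male"], n),
            "histologic_variant": rng.choice(["Classic", "Tall cell variant"],
                                             n, p=[0.9, 0.1]),
            "extrathyroidal_extension": rng.integers(0, 2, n),
            "pT": rng.choice(["pT1", "pT2", "pT3", "pT4"], n),
            "pN": rng.choice(["pN0/NX", "pN1"], n),
            "driver_class": rng.choice(["RAS-like", "BRAF-like"], n),
            "mutation_count": rng.poisson(11, n),
            "cluster": rng.choice(["NMF1", "NMF2", "NMF3", "NMF4"], n),
            "recurrence": rng.integers(0, 2, n),  # independent of everything
        }, index=[f"s{i}" for i in range(n)])
        out = build_table2(clinical)
        uni = out["univariate"]
        for var, row in uni.iterrows():
            log_or = np.log(row["odds_ratio"])
            se = np.log(row["ci_high"] / row["odds_ratio"]) / 1.959964
            assert abs(log_or) < 3 * se, var

    def test_aggressive_variant_mapping(self):
        n = 8
        clinical = pd.DataFrame({
            "age": [40] * n, "sex": ["Female"] * n,
            "histologic_variant": ["Tall cell variant", "Columnar", "Hobnail",
                                   "Classic", "Follicular variant", "Classic",
                                   "Tall cell", "Classic"],
            "extrathyroidal_extension": [0] * n,
            "pT": ["pT1"] * n, "pN": ["pN0/NX"] * n,
            "driver_class": ["RAS-like"] * n, "mutation_count": [5] * n,
            "cluster": ["NMF1"] * n, "recurrence": [0, 1] * 4,
        }, index=[f"s{i}" for i in range(n)])
        from ptcnmf.clinical import dichotomize_clinical
        binary = dichotomize_clinical(clinical)
        assert binary["aggressive_variant"].tolist() == [1, 1, 1, 0, 0, 0, 1, 0]

    def test_missing_column_reported(self):
        with pytest.raises(KeyError, match="mutation_count"):
            build_table2(pd.DataFrame({"age": [50], "sex": ["Male"]}))

    def test_synthetic_cohort_end_to_end(self):
        cfg = SyntheticConfig(n_genes=100, n_samples=1500, seed=17)
        cohort = generate_cohort(cfg)
        out = build_table2(cohort.clinical)
        uni = out["univariate"]
        # planted elevated recurrence in NMF3 shows up as OR > 1
        assert uni.loc["nmf3", "odds_ratio"] > 1.0
        assert "nmf3" in out["selected"]
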