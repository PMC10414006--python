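"""SVD score, weighted kappa, descriptive tables, tests, screening, VIF, models."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bbbhotspots as b
from bbbhotspots.stats import UndefinedKappaError, summarize_variable, spearman_association


class TestTotalSvdScore:
    def test_all_markers_present_scores_four(self):
        assert b.total_svd_score(2, 1, 3, 2, 3) == 4

    def test_all_absent_scores_zero(self):
        assert b.total_svd_score(0, 0, 0, 0, 1) == 0

    def test_single_wmh_point(self):
        assert b.total_svd_score(0, 0, 2, 1, 1) == 1

    def test_pvh_three_gives_wmh_point_but_pvh_two_does_not(self):
        assert b.total_svd_score(0, 0, 0, 3, 0) == 1
        assert b.total_svd_score(0, 0, 0, 2, 0) == 0

    def test_exhaustive_lattice_spans_zero_to_four_monotonely(self):
        scores = set()
        for lac, cmb, dwmh, pvh, pvs in itertools.product(
            (0, 1, 3), (0, 1, 2), range(4), range(4), range(5)
        ):
            s = b.total_svd_score(lac, cmb, dwmh, pvh, pvs)
            scores.add(s)
            assert 0 <= s <= 4
            # monotone non-decreasing in each marker
            assert b.total_svd_score(lac + 1, cmb, dwmh, pvh, pvs) >= s
            if dwmh < 3:
                assert b.total_svd_score(lac, cmb, dwmh + 1, pvh, pvs) >= s
        assert scores == {0, 1, 2, 3, 4}

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError):
            b.total_svd_score(0, 0, 4, 0, 0)


class TestWeightedKappa:
    def test_identical_ratings_give_one(self):
        ratings = [0, 1, 2, 1, 0, 2, 2, 1]
        assert b.weighted_kappa(ratings, ratings) == pytest.approx(1.0)

    def test_reversed_binary_scale_gives_minus_one(self):
        a = [0, 0, 1, 1]
        bb = [1, 1, 0, 0]
        assert b.weighted_kappa(a, bb) == pytest.approx(-1.0)

    def test_contingency_table_matches_hand_formula(self):
        # printed 3x3 table [[4,1,0],[1,3,1],[0,1,4]] expanded to vectors
        table = np.array([[4, 1, 0], [1, 3, 1], [0, 1, 4]])
        a, bb = [], []
        for i in range(3):
            for j in range(3):
                a += [i] * table[i, j]
                bb += [j] * table[i, j]
        n = table.sum()
        w = np.abs(np.subtract.outer(np.arange(3), np.arange(3))) / 2
        obs = table / n
        exp = np.outer(obs.sum(1), obs.sum(0))
        expected = 1 - (w * obs).sum() / (w * exp).sum()
        assert b.weighted_kappa(a, bb) == pytest.approx(expected)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 60)
        bb = np.clip(a + rng.integers(-1, 2, 60), 0, 3)
        ours = b.weighted_kappa(a, bb)
        theirs = cohen_kappa_score(a, bb, weights="linear")
        assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=5, max_size=40))
    def test_symmetric_in_arguments(self, a):
        rng = np.random.default_rng(len(a))
        bb = rng.integers(0, 4, len(a))
        if len(set(a) | set(bb.tolist())) < 2:
            return
        assert b.weighted_kappa(a, bb) == pytest.approx(b.weighted_kappa(bb, a))

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedKappaError):
            b.weighted_kappa([1, 1, 1], [1, 1, 1])


class TestDescriptives:
    def test_mean_sd_formatting(self):
        assert summarize_variable([1, 2, 3], "continuous") == "2.0 (1.0)"

    def test_binary_counts_and_percent(self):
        v = [1] * 31 + [0] * 38  # 31 of 69
        assert summarize_variable(v, "binary") == "31 (44.9)"

    def test_median_iqr_order_statistics(self):
        assert summarize_variable([0, 1, 3, 6, 9], "ordinal") == "3 (1–6)"

    def test_cohort_table_groups(self):
        df = pd.DataFrame(
            {"age": [60, 62, 58, 50, 52], "female": [1, 0, 1, 0, 1],
             "grp": ["a", "a", "a", "b", "b"]}
        )
        t = b.cohort_table(df, {"age": "continuous", "female": "binary"}, group="grp")
        assert set(t.columns) == {"all", "a", "b"}
        with pytest.raises(ValueError, match="empty"):
            b.cohort_table(df.iloc[:0], {"age": "continuous"})


class TestCompareGroups:
    def _df(self, a, bb, name="v"):
        return pd.DataFrame({name: list(a) + list(bb), "grp": ["a"] * len(a) + ["b"] * len(bb)})

    def test_constant_variable_not_applicable(self):
        res = b.compare_groups(self._df([1, 1, 1], [1, 1, 1]), "v", "grp")
        assert not res.applicable

    def test_fisher_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        # 2x2 table [[3,1],[1,3]]
        df = self._df([1, 1, 1, 0], [1, 0, 0, 0], name="v")
        res = b.compare_groups(df, "v", "grp", kind="binary")
        assert res.test == "fisher_exact"
        # two-sided Fisher p by enumerating tables with probability <= observed
        M, n, N = 8, 4, 4  # total, successes, draws in group a
        probs = [hypergeom.pmf(k, M, n, N) for k in range(5)]
        p_obs = hypergeom.pmf(3, M, n, N)
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert res.p == pytest.approx(expected, rel=1e-8)

    def test_chi_square_on_strongly_imbalanced_risk_factor(self):
        # hypertension-style 2x2: 34/42 vs 10/27 exposed
        v = [1] * 34 + [0] * 8 + [1] * 10 + [0] * 17
        g = ["sporadic"] * 42 + ["cadasil"] * 27
        res = b.compare_groups(pd.DataFrame({"v": v, "grp": g}), "v", "grp", kind="binary")
        assert res.test == "chi_square"
        assert res.p < 0.001

    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(6)
        df = self._df(rng.normal(0, 1, 40), rng.normal(1, 1, 40))
        res = b.compare_groups(df, "v", "grp", kind="continuous")
        assert res.test == "student_t"

    def test_ordinal_uses_mann_whitney(self):
        df = self._df([0, 1, 2, 2, 3, 1], [1, 2, 3, 3, 3, 2])
        res = b.compare_groups(df, "v", "grp", kind="ordinal")
        assert res.test == "mann_whitney_u"

    def test_spearman_for_ordinal_pairs(self):
        df = pd.DataFrame({"a": [0, 1, 2, 3, 3, 2], "b": [0, 1, 1, 3, 2, 2]})
        res = spearman_association(df, "a", "b")
        assert res.test == "spearman"
        assert res.statistic > 0


class TestScreen:
    def test_strict_inequality_boundary(self):
        res = pd.DataFrame({"variable": ["x", "y", "z"], "p": [0.10, 0.099, 0.5]})
        assert b.univariable_screen(res) == ["y"]

    def test_always_included_vascular_measures(self):
        res = pd.DataFrame({"variable": ["x"], "p": [0.5]})
        out = b.univariable_screen(res, always_include=("ps_nawm", "cvr_wmh"))
        assert out == ["ps_nawm", "cvr_wmh"]

    def test_matches_hand_filter(self):
        rng = np.random.default_rng(1)
        res = pd.DataFrame({"variable": [f"v{i}" for i in range(30)], "p": rng.random(30)})
        expected = [f"v{i}" for i in range(30) if res["p"][i] < 0.1]
        assert b.univariable_screen(res) == expected


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1], "b": [1, 1, -1, -1, 1, 1][:6]})
        X["b"] = [1, 1, -1, -1, 1, -1]
        vif = b.vif_screen(X)
        if abs(np.corrcoef(X["a"], X["b"])[0, 1]) < 1e-12:
            assert np.allclose(vif["vif"], 1.0)

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        vif = b.vif_screen(X)
        assert np.isinf(vif["vif"]).all()
        assert not vif["acceptable"].any()

    def test_known_correlation_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        n = 500
        a = rng.normal(size=n)
        bb = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        c = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": bb, "c": c})
        vif = b.vif_screen(X)
        # oracle: direct normal-equations solve for column a on (b, c)
        others = np.column_stack([np.ones(n), bb, c])
        beta = np.linalg.solve(others.T @ others, others.T @ a)
        resid = a - others @ beta
        r2 = 1 - resid @ resid / ((a - a.mean()) @ (a - a.mean()))
        assert vif.loc["a", "vif"] == pytest.approx(1 / (1 - r2), rel=1e-10)


class TestFitModels:
    def test_planted_effect_recovered_with_correct_sign(self):
        df = b.simulate_regression_records(300, effect_logodds=0.8, seed=3)
        res = b.fit_models(df, "hotspot_presence", ("exposure",), model_version=1)
        assert res.converged and not res.separation
        assert res.table.loc["exposure", "estimate"] > 0
        assert res.table.loc["exposure", "p"] < 0.05
        assert res.n_used == 300
        assert (res.table["ci_low"] <= res.table["ci_high"]).all()
        assert (res.vif["vif"] >= 1).all()

    def test_model2_adds_svd_type(self):
        df = b.simulate_regression_records(200, seed=4)
        r1 = b.fit_models(df, "hotspot_presence", ("exposure",), model_version=1)
        r2 = b.fit_models(df, "hotspot_presence", ("exposure",), model_version=2)
        assert "svd_type_cadasil" not in r1.table.index
        assert "svd_type_cadasil" in r2.table.index

    def test_perfect_separation_flagged_not_silent(self):
        rng = np.random.default_rng(8)
        df = b.simulate_regression_records(120, seed=8)
        df["sep"] = (df["hotspot_presence"] == 1).astype(float)  # perfectly separating
        res = b.fit_models(df, "hotspot_presence", ("sep",), model_version=1)
        assert res.separation or not res.converged

    def test_ordinal_count_model_recovers_sign(self):
        df = b.simulate_regression_records(400, count_effect=0.4, seed=10)
        res = b.fit_models(df, "hotspot_count", ("exposure",), model_version=1, outcome_type="count")
        assert res.converged
        assert res.table.loc["exposure", "estimate"] > 0

    def test_missing_covariate_complete_case_n(self):
        df = b.simulate_regression_records(150, seed=11)
        df.loc[:9, "exposure"] = np.nan  # 10 missing
        res = b.fit_models(df, "hotspot_presence", ("exposure",), model_version=1)
        assert res.n_used == 140
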