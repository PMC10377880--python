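import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from stfd import (
    demographics_tests,
    mann_whitney,
    pca_first_component,
    per_second_comparison,
    roc_auc,
    spearman_bonferroni,
)
from stfd.group_stats import validate_cohort_table

from _oracles import (
    chi2_2x2,
    exact_two_sided_p,
    mann_whitney_u_bruteforce,
    spearman_no_ties,
)


class TestMannWhitney:
    def test_fully_separated_small(self):
        cmp = mann_whitney([1, 2, 3], [4, 5, 6])
        assert cmp.u_statistic == 9.0
        assert cmp.p_value == pytest.approx(0.1)
        assert cmp.direction == "second"

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        cmp = mann_whitney(x, y)
        assert cmp.p_value == pytest.approx(exact_two_sided_p(x, y))

    def test_u_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, size=8).astype(float)
            y = rng.integers(0, 10, size=6).astype(float)
            cmp = mann_whitney(x, y)
            u_x = mann_whitney_u_bruteforce(x, y)
            assert cmp.u_statistic == pytest.approx(max(u_x, 48 - u_x))

    def test_identical_samples_midrank(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cmp = mann_whitney(x, x)
        assert cmp.u_statistic == pytest.approx(len(x) ** 2 / 2)
        assert cmp.direction == "tie"

    def test_separated_27_15_hits_ceiling(self, rng):
        x = rng.normal(loc=10.0, size=27)
        y = rng.normal(loc=0.0, size=15)
        cmp = mann_whitney(x, y)
        assert cmp.u_statistic == 405.0 == cmp.n1 * cmp.n2
        assert cmp.direction == "first"
        assert cmp.p_value < 0.001

    def test_empty_sample_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_order_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=9)
        a = mann_whitney(x, y)
        b = mann_whitney(rng.permutation(x), rng.permutation(y))
        assert a.u_statistic == b.u_statistic and a.p_value == b.p_value


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11]
        labels = ["groupB"] * 3 + ["groupA"] * 2
        assert roc_auc(scores, labels) == 1.0

    def test_identical_scores(self):
        assert roc_auc([5.0] * 6, ["groupA"] * 3 + ["groupB"] * 3) == 0.5

    def test_one_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], ["groupA", "groupA"])

    def test_u_identity_and_sklearn_oracle(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(2, 15))
            n2 = int(rng.integers(2, 15))
            scores = rng.integers(0, 8, size=n1 + n2).astype(float)
            labels = np.array(["groupA"] * n1 + ["groupB"] * n2)
            auc = roc_auc(scores, labels)
            u_a = mann_whitney_u_bruteforce(scores[:n1], scores[n1:])
            assert auc == pytest.approx(u_a / (n1 * n2))
            assert auc == pytest.approx(
                roc_auc_score(labels == "groupA", scores)
            )


class TestSpearman:
    def _table(self, fd, **scores):
        return pd.DataFrame({"mean_fd": fd, **scores})

    def test_monotone_transform_rho_one(self):
        fd = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = spearman_bonferroni(self._table(fd, updrs3=np.exp(fd)), ["updrs3"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_negation_rho_minus_one(self):
        fd = np.array([1.0, 2.0, 3.0, 4.0])
        out = spearman_bonferroni(self._table(fd, updrs3=-fd), ["updrs3"])
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_formula_oracle_no_ties(self, rng):
        fd = rng.permutation(5).astype(float)
        score = rng.permutation(5).astype(float)
        out = spearman_bonferroni(self._table(fd, updrs3=score), ["updrs3"])
        assert out.loc[0, "rho"] == pytest.approx(spearman_no_ties(fd, score))

    def test_bonferroni_multiplier(self, rng):
        fd = rng.normal(size=10)
        table = self._table(
            fd,
            updrs3=rng.normal(size=10),
            moca=rng.normal(size=10),
            mmp=rng.normal(size=10),
        )
        out = spearman_bonferroni(table, ["updrs3", "moca", "mmp"])
        assert (out["n_comparisons"] == 3).all()
        valid = out["p_raw"].notna()
        assert (out.loc[valid, "p_adjusted"] >= out.loc[valid, "p_raw"]).all()
        assert (out.loc[valid, "p_adjusted"] <= 1.0).all()

    def test_constant_column_reported_missing(self):
        fd = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = spearman_bonferroni(self._table(fd, updrs3=np.ones(5)), ["updrs3"])
        assert np.isnan(out.loc[0, "rho"])
        assert out.loc[0, "reason"] == "constant column"

    def test_too_few_rows_reported(self):
        fd = np.array([1.0, 2.0, 3.0])
        out = spearman_bonferroni(self._table(fd, updrs3=fd), ["updrs3"])
        assert out.loc[0, "reason"] == "fewer than 4 complete rows"

    def test_pairwise_complete(self, rng):
        fd = rng.normal(size=8)
        score = rng.normal(size=8)
        score[2] = np.nan
        out = spearman_bonferroni(self._table(fd, updrs3=score), ["updrs3"])
        assert out.loc[0, "n"] == 7


class TestPca:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"updrs3": x, "moca": 3 * x + 1})
        fraction, _ = pca_first_component(table, ["updrs3", "moca"])
        assert fraction == pytest.approx(1.0)

    def test_independent_pair_tends_to_half(self, rng):
        n = 20_000
        table = pd.DataFrame(
            {"updrs3": rng.normal(size=n), "moca": rng.normal(size=n)}
        )
        fraction, _ = pca_first_component(table, ["updrs3", "moca"])
        assert fraction == pytest.approx(0.5, abs=0.02)

    def test_one_factor_model_analytic(self, rng):
        n, loading = 4000, 0.95
        f = rng.normal(size=n)
        cols = {}
        for name in ("updrs3", "hoehn_yahr", "moca", "mmp"):
            cols[name] = loading * f + np.sqrt(1 - loading**2) * rng.normal(size=n)
        fraction, scores = pca_first_component(pd.DataFrame(cols))
        analytic = (1 + 3 * loading**2) / 4  # top eigenvalue of the equicorrelation
        assert fraction == pytest.approx(analytic, abs=0.05)
        assert len(scores) == n

    def test_fraction_bounds_and_sum(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 3)), columns=["updrs3", "moca", "mmp"])
        fraction, _ = pca_first_component(table, ["updrs3", "moca", "mmp"])
        assert 1 / 3 <= fraction <= 1.0

    def test_requires_complete_cases(self):
        table = pd.DataFrame({"updrs3": [1.0, np.nan], "moca": [2.0, 3.0]})
        with pytest.raises(ValueError, match="three complete"):
            pca_first_component(table, ["updrs3", "moca"])


class TestPerSecond:
    def test_ceiling_under_uniform_dominance(self, rng):
        t = 120
        a = rng.normal(loc=5.0, size=(4, t))
        b = rng.normal(loc=0.0, size=(3, t))
        cmp = per_second_comparison({"groupA": a, "groupB": b})
        assert cmp.u_statistic == t * t == 14_400

    def test_identical_curves_half(self):
        curve = np.arange(10.0).reshape(1, -1)
        cmp = per_second_comparison({"groupA": curve, "groupB": curve.copy()})
        assert cmp.u_statistic == pytest.approx(50.0)

    def test_hand_built_t5_matches_enumeration(self):
        a = np.array([[1.5, 4.2, 2.1, 6.3, 3.4]])
        b = np.array([[2.0, 3.1, 1.0, 5.5, 7.7]])
        cmp = per_second_comparison({"groupA": a, "groupB": b})
        u = mann_whitney_u_bruteforce(a[0], b[0])
        assert cmp.u_statistic == pytest.approx(max(u, 25 - u))
        assert cmp.p_value == pytest.approx(exact_two_sided_p(a[0], b[0]))

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            per_second_comparison(
                {"groupA": np.ones((2, 5)), "groupB": np.ones((2, 6))}
            )

    def test_group_averaging(self):
        # two subjects averaging to a dominated curve
        a = np.array([[10.0, 10.0, 10.0], [0.0, 0.0, 0.0]])  # mean = 5
        b = np.array([[4.0, 4.0, 4.0]])
        cmp = per_second_comparison({"groupA": a, "groupB": b})
        assert cmp.u_statistic == 9.0


class TestDemographics:
    def _table(self, sexes, groups, ages=None):
        n = len(sexes)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "sex": sexes,
                "age": ages if ages is not None else np.arange(n, dtype=float),
                "education": np.arange(n, dtype=float)[::-1],
            }
        )

    def test_balanced_table_chi2_zero(self):
        table = self._table(
            ["F", "F", "M", "M"] * 2,
            ["groupA"] * 4 + ["groupB"] * 4,
        )
        out = demographics_tests(table)
        assert out["sex"]["chi2"] == pytest.approx(0.0)

    def test_chi2_direct_formula(self):
        # contingency [[12, 15], [7, 8]]
        sexes = ["F"] * 12 + ["M"] * 15 + ["F"] * 7 + ["M"] * 8
        groups = ["groupA"] * 27 + ["groupB"] * 15
        out = demographics_tests(self._table(sexes, groups))
        assert out["sex"]["chi2"] == pytest.approx(chi2_2x2([[12, 15], [7, 8]]))

    def test_zero_margin_error(self):
        table = self._table(["F"] * 6, ["groupA"] * 3 + ["groupB"] * 3)
        with pytest.raises(ValueError, match="margin"):
            demographics_tests(table)

    def test_age_education_u_tests_present(self):
        table = self._table(
            ["F", "M"] * 4, ["groupA"] * 4 + ["groupB"] * 4
        )
        out = demographics_tests(table)
        assert set(out) == {"sex", "age", "education"}
        assert 0 <= out["age"]["u_statistic"] <= 16


class TestCohortTable:
    def test_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_cohort_table(pd.DataFrame({"subject_id": ["a"]}))

    def test_duplicate_subjects(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "a"], "group": ["groupA"] * 2, "mean_fd": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort_table(df)

    def test_row_order_invariance(self, rng):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "group": ["groupA"] * 7 + ["groupB"] * 5,
                "mean_fd": rng.normal(size=12),
            }
        )
        shuffled = df.sample(frac=1.0, random_state=3)
        a = roc_auc(df["mean_fd"], df["group"])
        b = roc_auc(shuffled["mean_fd"], shuffled["group"])
        assert a == pytest.approx(b)
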