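"""Tests for transforms, group tests, compact letters and the mixed-model screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ntracer import (
    StudyDesign,
    assumption_checks,
    compact_letter_display,
    log_transform,
    mixed_model_screen,
    one_sample_t,
    oneway_anova_letters,
    quantile_transform,
    welch_or_student_t,
)


class TestQuantileTransform:
    def test_three_values_symmetric(self):
        scores = quantile_transform([10.0, 30.0, 20.0])
        order = np.argsort([10.0, 30.0, 20.0])
        assert scores[order[1]] == pytest.approx(0.0, abs=1e-12)
        assert scores[order[0]] == pytest.approx(-scores[order[2]], abs=1e-12)

    def test_monotone_in_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        scores = quantile_transform(x)
        assert np.all(np.diff(scores[np.argsort(x)]) > 0)

    def test_matches_rank_oracle_with_ties(self):
        x = np.array([3.0, 1.0, 3.0, 2.0, 5.0])
        # brute-force oracle: average ranks then Blom inverse-normal
        ranks = sps.rankdata(x)
        expected = sps.norm.ppf((ranks - 3 / 8) / (len(x) + 1 / 4))
        assert quantile_transform(x) == pytest.approx(expected, abs=1e-12)

    def test_depends_on_ranks_only(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        assert quantile_transform(x) == pytest.approx(quantile_transform(x**3), abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            quantile_transform([1.0, 1.0, 1.0])


class TestLogTransform:
    def test_known_values(self):
        out, ok = log_transform([np.e, 1.0])
        assert out == pytest.approx([1.0, 0.0])
        assert ok.all()

    def test_nonpositive_flagged_not_fatal(self):
        out, ok = log_transform([1.0, 0.0, -2.0, 10.0], base="10")
        assert list(ok) == [True, False, False, True]
        assert np.isnan(out[1]) and np.isnan(out[2])
        assert out[3] == pytest.approx(1.0)


class TestAssumptionChecks:
    def test_reports_shapiro_and_levene(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20)])
        groups = np.array(["a"] * 20 + ["b"] * 20)
        rep = assumption_checks(vals, groups)
        assert set(rep["shapiro"]) == {"a", "b"}
        assert 0 <= rep["levene_p"] <= 1

    def test_identical_groups_degenerate(self):
        vals = np.array([1.0] * 5 + [1.0] * 5)
        rep = assumption_checks(vals, np.array(["a"] * 5 + ["b"] * 5))
        assert rep["degenerate"]

    def test_tiny_group_skipped(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0, 3.0])
        rep = assumption_checks(vals, np.array(["a", "a", "b", "b", "b"]))
        assert rep["skipped"] == ["a"]


class TestAnovaLetters:
    def test_zero_variance_everywhere_shares_letter(self):
        vals = np.array([5.0] * 9)
        groups = np.repeat(["x", "y", "z"], 3)
        res = oneway_anova_letters(vals, groups)
        assert set(res.letters.values()) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(10, 1, 12)])
        groups = np.repeat(["lo", "hi"], 12)
        res = oneway_anova_letters(vals, groups)
        assert res.letters["lo"] != res.letters["hi"]
        assert res.p_value < 1e-6

    def test_f_statistic_matches_textbook_formula(self):
        # 3 groups x 4 observations, hand-computable
        data = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([2.0, 3.0, 4.0, 5.0]),
            "c": np.array([6.0, 7.0, 8.0, 9.0]),
        }
        vals = np.concatenate(list(data.values()))
        groups = np.repeat(list(data), 4)
        grand = vals.mean()
        ss_between = sum(4 * (v.mean() - grand) ** 2 for v in data.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
        f_expected = (ss_between / 2) / (ss_within / 9)
        res = oneway_anova_letters(vals, groups)
        assert res.f_statistic == pytest.approx(f_expected, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_letters(np.arange(4.0), np.repeat(["a"], 4))


class TestCompactLetterDisplay:
    def test_share_letter_iff_not_significant(self):
        labels = ["a", "b", "c"]
        pvals = {
            frozenset(("a", "b")): 0.80,
            frozenset(("a", "c")): 0.001,
            frozenset(("b", "c")): 0.001,
        }
        letters = compact_letter_display(labels, pvals)
        assert set(letters["a"]) & set(letters["b"])
        assert not set(letters["a"]) & set(letters["c"])
        assert not set(letters["b"]) & set(letters["c"])

    def test_chain_pattern(self):
        # a ~ b, b ~ c, but a != c: b must share a letter with both
        pvals = {
            frozenset(("a", "b")): 0.5,
            frozenset(("b", "c")): 0.5,
            frozenset(("a", "c")): 0.01,
        }
        letters = compact_letter_display(["a", "b", "c"], pvals)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestTTests:
    def test_identical_samples_t_zero(self):
        res = welch_or_student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_pooled_t(self):
        a = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sp2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        res = welch_or_student_t(a, b, equal_var=True)
        assert res.t == pytest.approx(t_expected, rel=1e-12)
        assert res.df == 8

    def test_zero_variance_convention(self):
        res = welch_or_student_t([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_one_sample_constant_flagged(self):
        res = one_sample_t([1.0, 1.0, 1.0], 0.0)
        assert np.isinf(res.t) and res.degenerate and res.p == 0.0

    def test_one_sample_matches_scipy(self):
        vals = np.array([0.1, -0.2, 0.3, 0.15, 0.05])
        res = one_sample_t(vals, 0.0)
        ref = sps.ttest_1samp(vals, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestMixedModelScreen:
    @staticmethod
    def _frame(rng, species_effect=0.0):
        design = StudyDesign()
        from ntracer import generate_design

        df = generate_design(design).drop_duplicates(
            subset=["site", "habitat", "quadrat", "species"]
        )
        y = rng.normal(0, 1, len(df))
        y = y + np.where(df["species"] == "invasive", species_effect, 0.0)
        return df.assign(y=y)

    def test_null_rejection_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 60
        for _ in range(n_reps):
            tab = mixed_model_screen(self._frame(rng), "y")
            p = tab.loc[tab["term"] == "C(species)", "p_value"].iloc[0]
            rejections += p < 0.05
        # binomial(60, 0.05): central 99% region is roughly [0, 8]
        assert rejections <= 8

    def test_species_effect_detected(self):
        rng = np.random.default_rng(8)
        detected = 0
        for _ in range(15):
            tab = mixed_model_screen(self._frame(rng, species_effect=3.0), "y")
            p = tab.loc[tab["term"] == "C(species)", "p_value"].iloc[0]
            detected += p < 0.05
        assert detected >= 14  # 3-sd effect at n = 72 rows: essentially always found

    def test_single_site_downgrades_to_ols(self):
        rng = np.random.default_rng(9)
        df = self._frame(rng)
        df = df[df["site"] == "site1"]
        tab = mixed_model_screen(df, "y")
        assert (tab["method"] == "ols_anova").all()

    def test_constant_response_degenerate(self):
        df = self._frame(np.random.default_rng(10)).assign(y=1.0)
        tab = mixed_model_screen(df, "y")
        assert (tab["method"] == "degenerate").all()
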