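"""Statistical decision chain: Lilliefors KS gate, Friedman with exact
enumeration, Steel–Dwass all-pairs comparisons, RM-ANOVA, and branching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_friedman
from tacsfx import stats
from tacsfx.spectral import InputError
from tacsfx.stats import (
    friedman_test,
    ks_normality,
    naive_ks,
    rm_anova_bonferroni,
    run_branch,
    steel_dwass,
)


class TestKsGate:
    def test_too_few_or_constant_rejected(self):
        with pytest.raises(InputError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            ks_normality(np.full(10, 2.0))

    def test_calibrated_under_normal_null(self):
        rng = np.random.default_rng(100)
        passes = sum(
            ks_normality(rng.standard_normal(2000)) > 0.05 for _ in range(100)
        )
        assert passes >= 90  # ~95 expected at nominal 5% level

    def test_rejects_lognormal_alternative(self):
        rng = np.random.default_rng(101)
        rejects = sum(
            ks_normality(np.exp(rng.standard_normal(2000))) < 0.05
            for _ in range(100)
        )
        assert rejects == 100

    def test_naive_ks_exposed_and_less_powerful(self):
        rng = np.random.default_rng(102)
        x = rng.standard_normal(500)
        # naive KS with plug-in parameters is conservative: larger p than
        # the Lilliefors-corrected gate on the same data
        assert naive_ks(x) >= ks_normality(x)


class TestFriedman:
    def test_three_conditions_two_df(self):
        rng = np.random.default_rng(0)
        res = friedman_test(rng.normal(size=(12, 3)), exact=False)
        assert res.df == 2

    def test_identical_blocks_give_zero_statistic(self):
        res = friedman_test(np.ones((6, 3)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_on_untied_data(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 4))
        res = friedman_test(x, exact=False)
        ref = friedmanchisquare(*x.T)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_p_matches_brute_force_enumeration(self):
        table = np.array(
            [
                [1.2, 3.4, 2.2],
                [0.7, 2.9, 2.8],
                [1.1, 1.0, 3.0],
                [2.2, 2.5, 2.4],
                [0.3, 1.9, 1.4],
            ]
        )
        res = friedman_test(table, exact=True)
        stat_oracle, p_oracle = brute_friedman(table)
        assert res.statistic == pytest.approx(stat_oracle)
        assert res.extra["p_exact"] == pytest.approx(p_oracle)

    def test_asymptotic_close_to_exact_in_rejection_region(self):
        # the chi-squared approximation tracks the lumpy exact null well in
        # the decision-relevant tail (p <= 0.2); mid-range p at b <= 6 can
        # differ by > 0.1 because the exact distribution has few atoms
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(60):
            b = int(rng.integers(4, 7))
            table = rng.normal(size=(b, 3))
            res = friedman_test(table, exact=True)
            if res.extra["p_exact"] <= 0.2:
                assert abs(res.p_value - res.extra["p_exact"]) < 0.05
                checked += 1
        assert checked >= 5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(9, 3))
        base = friedman_test(x, exact=False).statistic
        for f in (np.exp, np.cbrt, lambda v: 5 * v - 2):
            assert friedman_test(f(x), exact=False).statistic == pytest.approx(base)

    def test_missing_cell_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(InputError):
            friedman_test(x)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            friedman_test(rng.standard_normal((16, 3)), exact=False).p_value < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065


class TestSteelDwass:
    def test_identical_groups_null_result(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = steel_dwass([g, g.copy()], exact=False)
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p_adjusted > 0.95

    def test_relabeling_preserves_magnitudes(self):
        rng = np.random.default_rng(2)
        gs = {lbl: rng.normal(size=6) for lbl in ("x", "y", "z")}
        fwd = {r.pair: abs(r.statistic) for r in steel_dwass(gs, exact=False)}
        rev = {
            r.pair: abs(r.statistic)
            for r in steel_dwass(dict(reversed(gs.items())), exact=False)
        }
        for (a, b), v in fwd.items():
            assert rev[(b, a)] == pytest.approx(v)

    def test_adjusted_p_tracks_exact_enumeration(self):
        groups = [
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([10.0, 11.0, 12.0, 13.0]),
            np.array([20.0, 21.0, 22.0, 23.0]),
        ]
        for res in steel_dwass(groups):
            assert res.p_exact is not None
            assert abs(res.p_adjusted - res.p_exact) <= 0.01

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            gs = [rng.standard_normal(16) for _ in range(3)]
            hits += any(
                r.p_adjusted < 0.05 for r in steel_dwass(gs, exact=False)
            )
        assert hits / n_rep <= 0.065

    def test_tiny_group_rejected(self):
        with pytest.raises(InputError):
            steel_dwass([np.array([1.0]), np.array([1.0, 2.0])])


class TestRmAnova:
    def test_all_equal_cells_give_zero_f(self):
        rows = [
            {"unit": u, "condition": c, "phase": p, "value": 1.0}
            for u in range(4)
            for c in ("a", "b", "c")
            for p in ("pre", "post")
        ]
        res = rm_anova_bonferroni(pd.DataFrame(rows))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_f_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(9)
        units, conds = 6, ("a", "b", "c")
        values = rng.normal(size=(units, 3))
        rows = [
            {"unit": u, "condition": c, "value": values[u, j]}
            for u in range(units)
            for j, c in enumerate(conds)
        ]
        res = rm_anova_bonferroni(pd.DataFrame(rows), time=None)
        # dense one-way within-subject sums of squares
        grand = values.mean()
        ss_cond = units * np.sum((values.mean(axis=0) - grand) ** 2)
        ss_subj = len(conds) * np.sum((values.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((values - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        df_c, df_e = len(conds) - 1, (units - 1) * (len(conds) - 1)
        f_oracle = (ss_cond / df_c) / (ss_err / df_e)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-8)
        assert res.df == (df_c, df_e)

    def test_bonferroni_multiplies_raw_p(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(10)
        values = rng.normal(size=(8, 3)) + np.array([0.0, 0.5, 1.0])
        rows = [
            {"unit": u, "condition": c, "value": values[u, j]}
            for u in range(8)
            for j, c in enumerate(("a", "b", "c"))
        ]
        res = rm_anova_bonferroni(pd.DataFrame(rows), time=None)
        for pw in res.pairwise:
            i, j = [ord(x) - ord("a") for x in pw.pair]
            raw = ttest_rel(values[:, i], values[:, j]).pvalue
            assert pw.p_adjusted == pytest.approx(min(1.0, raw * 3))

    def test_unbalanced_design_rejected(self):
        rows = [
            {"unit": 0, "condition": "a", "value": 1.0},
            {"unit": 0, "condition": "b", "value": 2.0},
            {"unit": 1, "condition": "a", "value": 1.0},
        ]
        with pytest.raises(InputError):
            rm_anova_bonferroni(pd.DataFrame(rows), time=None)


class TestRunBranch:
    @staticmethod
    def _frame(values: np.ndarray) -> pd.DataFrame:
        units, conds = values.shape
        return pd.DataFrame(
            [
                {"unit": u, "condition": c, "value": values[u, j]}
                for u in range(units)
                for j, c in enumerate("abc"[:conds])
            ]
        )

    def test_lognormal_data_takes_nonparametric_branch(self):
        rng = np.random.default_rng(12)
        values = np.exp(rng.standard_normal((16, 3)) * 1.5)
        res = run_branch(self._frame(values))
        assert res.extra["branch"] == "nonparametric"
        assert res.test_name == "friedman"
        assert len(res.pairwise) == 3

    def test_gaussian_data_mostly_parametric(self):
        # with the any-condition-fails gate at alpha = 0.05 and 3
        # conditions the parametric rate is (1 - alpha_eff)^3 ~ 0.86
        rng = np.random.default_rng(11)
        parametric = sum(
            run_branch(self._frame(rng.standard_normal((16, 3)))).extra["branch"]
            == "parametric"
            for _ in range(100)
        )
        assert parametric >= 80

    def test_alpha_zero_forces_parametric(self):
        rng = np.random.default_rng(13)
        values = np.exp(rng.standard_normal((10, 3)))
        res = run_branch(self._frame(values), alpha=0.0)
        assert res.extra["branch"] == "parametric"

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_branch_label_always_recorded(self, seed):
        rng = np.random.default_rng(seed)
        res = run_branch(self._frame(rng.standard_normal((8, 3))))
        assert res.extra["branch"] in ("parametric", "nonparametric")
        assert set(res.extra["ks_p"]) == {"a", "b", "c"}
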