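"""Mixed repeated-measures ANOVA, sphericity, post-hoc, correlation, OLS.

Cross-validated against independent implementations wherever one exists:
pingouin's mixed ANOVA (balanced one-within designs), statsmodels AnovaRM
(pure within designs), scipy's one-way ANOVA on the between-only collapse,
and closed-form paired-t / studentized-range identities.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from dropload.cohort import CohortDesign, make_cohort
from dropload.rmstats import (
    IncompleteDesignError,
    RankDeficiencyError,
    UndefinedCorrelationError,
    linfit,
    mauchly_test,
    mixed_rm_anova,
    one_way_anova,
    pearson_corr,
    tukey_posthoc,
)


def rm_frame(y, subject_prefix="s", **factors):
    """Long frame from a (subjects x cells) array and factor level lists."""
    import itertools

    names = list(factors)
    cells = list(itertools.product(*factors.values()))
    rows = []
    for i, row in enumerate(y):
        for cell, v in zip(cells, row):
            rows.append({"subject_id": f"{subject_prefix}{i}",
                         **dict(zip(names, cell)), "value": v})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_level_within_equals_paired_t_squared(self, rng):
        y = rng.normal(0, 1, size=(10, 2))
        y[:, 1] += 0.8
        df = rm_frame(y, w=["w1", "w2"])
        res = mixed_rm_anova(df, between=None, within=("w",))[0]
        t, p = sps.ttest_rel(y[:, 1], y[:, 0])
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_constant_data_gives_zero_f(self):
        y = np.full((6, 4), 3.7)
        df = rm_frame(y, c=["S", "FP"], h=[0.5, 1.0])
        df["grp"] = np.repeat(["A", "B"], 12)
        for res in mixed_rm_anova(df, between="grp", within=("c", "h")):
            assert res.f_stat == 0.0
            assert res.partial_eta2 == 0.0

    def test_matches_pingouin_on_balanced_mixed_design(self, rng):
        y = rng.normal(10, 2, size=(21, 3)) + rng.normal(0, 2, size=(21, 1))
        df = rm_frame(y, w=["w1", "w2", "w3"])
        df["grp"] = np.repeat(["A", "B", "C"], 21)
        mine = {r.effect: r for r in mixed_rm_anova(df, between="grp", within=("w",))}
        ref = pg.mixed_anova(df, dv="value", within="w", subject="subject_id",
                             between="grp").set_index("Source")
        assert mine["grp"].f_stat == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine["w"].f_stat == pytest.approx(ref.loc["w", "F"], rel=1e-9)
        assert mine["grp × w"].f_stat == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine["w"].partial_eta2 == pytest.approx(
            ref.loc["w", "np2"], rel=1e-9
        )

    def test_matches_anovarm_on_two_within_factors(self, rng):
        y = rng.normal(0, 1, size=(12, 6))
        df = rm_frame(y, a=["a1", "a2"], b=["b1", "b2", "b3"])
        mine = {r.effect: r for r in mixed_rm_anova(df, between=None,
                                                    within=("a", "b"))}
        ref = AnovaRM(df, "value", "subject_id", within=["a", "b"]).fit().anova_table
        for eff, key in [("a", "a"), ("b", "b"), ("a × b", "a:b")]:
            assert mine[eff].f_stat == pytest.approx(
                ref.loc[key, "F Value"], rel=1e-9
            )
            assert mine[eff].p_value == pytest.approx(
                ref.loc[key, "Pr > F"], rel=1e-9
            )

    def test_between_collapse_equals_one_way_closed_form(self, rng):
        y = rng.normal(5, 1, size=(18, 4))
        df = rm_frame(y, c=["S", "FP"], h=[0.5, 1.0])
        df["grp"] = np.repeat(["A", "B", "C"], 24)
        res = {r.effect: r for r in mixed_rm_anova(df, between="grp",
                                                   within=("c", "h"))}
        subj_means = y.mean(axis=1)
        f_ref, p_ref = sps.f_oneway(subj_means[:6], subj_means[6:12],
                                    subj_means[12:])
        assert res["grp"].f_stat == pytest.approx(f_ref, rel=1e-10)
        assert res["grp"].p_value == pytest.approx(p_ref, rel=1e-10)

    def test_balanced_ss_reconstruct_total(self, rng):
        # with equal group sizes the effect and error sums of squares of all
        # strata form an orthogonal decomposition of the total corrected SS
        y = rng.normal(0, 1, size=(12, 4))
        df = rm_frame(y, c=["S", "FP"], h=[0.5, 1.0])
        df["grp"] = np.repeat(["A", "B"], 24)
        results = mixed_rm_anova(df, between="grp", within=("c", "h"))
        ss_total = ((y - y.mean()) ** 2).sum()
        ss_sum = sum(r.ss_effect for r in results)
        # each stratum's error SS is shared by the effects tested against it
        strata = {r.effect.removeprefix("grp × "): r.ss_error for r in results}
        ss_sum += sum(strata.values())
        assert ss_sum == pytest.approx(ss_total, rel=1e-9)

    def test_partial_eta2_bounded(self, rng):
        y = rng.normal(0, 1, size=(9, 4))
        df = rm_frame(y, c=["S", "FP"], h=[0.5, 1.0])
        df["grp"] = np.repeat(np.tile(["A", "B", "C"], 3), 4)
        for r in mixed_rm_anova(df, between="grp", within=("c", "h")):
            assert 0.0 <= r.partial_eta2 <= 1.0

    def test_incomplete_design_lists_subjects(self, rng):
        y = rng.normal(0, 1, size=(5, 4))
        df = rm_frame(y, c=["S", "FP"], h=[0.5, 1.0])
        df = df[~((df.subject_id == "s2") & (df.c == "FP") & (df.h == 1.0))]
        with pytest.raises(IncompleteDesignError, match="s2"):
            mixed_rm_anova(df, between=None, within=("c", "h"))


class TestMauchly:
    def test_two_level_factor_is_trivially_spherical(self, rng):
        y = rng.normal(0, 1, size=(8, 2))
        df = rm_frame(y, w=["w1", "w2"])
        assert mauchly_test(df, "w") == (1.0, 1.0, 1.0)

    def test_matches_pingouin_single_group(self, rng):
        y = rng.normal(0, 1, size=(15, 3)) * np.array([1.0, 1.5, 2.5])
        df = rm_frame(y, w=["w1", "w2", "w3"])
        w, p, eps = mauchly_test(df, "w")
        ref = pg.sphericity(df, dv="value", within="w", subject="subject_id")
        eps_ref = pg.epsilon(df, dv="value", within="w", subject="subject_id",
                             correction="gg")
        assert w == pytest.approx(ref.W, rel=1e-9)
        assert p == pytest.approx(ref.pval, rel=1e-9)
        assert eps == pytest.approx(eps_ref, rel=1e-9)

    def test_null_rejection_rate_in_binomial_band(self):
        # iid normal data are compound-symmetric, so sphericity holds; the
        # test's size at alpha=0.05 stays inside the 95% binomial band
        rng = np.random.default_rng(2718)
        n_reps, n_subj = 500, 50
        rejections = 0
        for _ in range(n_reps):
            y = rng.normal(0, 1, size=(n_subj, 3))
            df = rm_frame(y, w=["w1", "w2", "w3"])
            _, p, _ = mauchly_test(df, "w")
            rejections += p < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) <= band

    def test_zero_variance_is_rank_deficient(self):
        y = np.full((10, 3), 2.0)
        df = rm_frame(y, w=["w1", "w2", "w3"])
        with pytest.raises(RankDeficiencyError):
            mauchly_test(df, "w")

    def test_too_few_subjects_rejected(self, rng):
        y = rng.normal(0, 1, size=(2, 4))
        df = rm_frame(y, w=["w1", "w2", "w3", "w4"])
        with pytest.raises(RankDeficiencyError):
            mauchly_test(df, "w")


class TestTukey:
    def test_identical_group_means_give_p_near_one(self):
        # same subject values in every group: all pairwise differences are 0
        y = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (3, 2))
        df = rm_frame(y, w=["w1", "w2"])
        df["grp"] = np.repeat(["A", "B", "C"], 8)
        tab = tukey_posthoc(df, "grp", between="grp")
        assert (tab["p_value"] > 0.999).all()

    def test_two_groups_reduce_to_t_test(self, rng):
        y = rng.normal(0, 1, size=(16, 2))
        y[8:] += 0.9
        df = rm_frame(y, w=["w1", "w2"])
        df["grp"] = np.repeat(["A", "B"], 16)
        tab = tukey_posthoc(df, "grp", between="grp")
        subj = y.mean(axis=1)
        t, p = sps.ttest_ind(subj[:8], subj[8:])
        assert tab["q"].iloc[0] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-9)
        assert tab["p_value"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_two_level_within_reduces_to_paired_t(self, rng):
        y = rng.normal(0, 1, size=(12, 2))
        y[:, 1] += 0.5
        df = rm_frame(y, w=["w1", "w2"])
        tab = tukey_posthoc(df, "w", between=None)
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        assert tab["p_value"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_matches_statsmodels_between_groups(self, rng):
        y = rng.normal(0, 1, size=(24, 2))
        df = rm_frame(y, w=["w1", "w2"])
        df["grp"] = np.repeat(["A", "B", "C"], 16)
        tab = tukey_posthoc(df, "grp", between="grp")
        subj = y.mean(axis=1)
        ref = pairwise_tukeyhsd(subj, np.repeat(["A", "B", "C"], 8))
        np.testing.assert_allclose(
            sorted(tab["p_value"]), sorted(ref.pvalues), rtol=1e-6, atol=1e-8
        )

    def test_body_mass_group_separation(self):
        # cohort with published group means/SDs and sizes 83/38/50: the
        # youngest group differs from both older groups, which do not
        # differ from each other
        d = CohortDesign(seed=6, trials_per_condition=1)
        subjects = make_cohort(d, with_traces=False).subjects
        df = subjects.rename(columns={"mass_kg": "value"})
        df["dummy"] = "x"
        tab = tukey_posthoc(df, "age_group", between="age_group").set_index(
            ["level_a", "level_b"]
        )
        assert tab.loc[("I", "II"), "p_value"] < 0.05
        assert tab.loc[("I", "III"), "p_value"] < 0.05
        assert tab.loc[("II", "III"), "p_value"] > 0.05

    def test_single_level_effect_rejected(self, rng):
        y = rng.normal(0, 1, size=(5, 2))
        df = rm_frame(y, w=["w1", "w2"])
        df["grp"] = "A"
        with pytest.raises(ValueError):
            tukey_posthoc(df, "grp", between="grp")


class TestOneWay:
    def test_matches_scipy(self, rng):
        vals = rng.normal(0, 1, 30)
        groups = np.repeat(["A", "B", "C"], 10)
        vals[10:20] += 1.0
        res = one_way_anova(vals, groups)
        f_ref, p_ref = sps.f_oneway(vals[:10], vals[10:20], vals[20:])
        assert res.f_stat == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)


class TestCorrelationAndFit:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_matches_sum_formula_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = 0.4 * x + rng.normal(0, 1, 10)
        r, _ = pearson_corr(x, y)
        n = len(x)
        r_ref = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_linfit_exact_line(self):
        a, b, r2 = linfit([0.0, 1.0], [1.0, 3.0])
        assert (a, b, r2) == pytest.approx((1.0, 2.0, 1.0))

    def test_linfit_zero_slope(self, rng):
        x = np.arange(10.0)
        y = np.full(10, 2.5)
        _, b, _ = linfit(x, y)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_linfit_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linfit(np.ones(5), np.arange(5.0))

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.normal(0, 2, 40)
        y = 1.3 - 0.7 * x + rng.normal(0, 1, 40)
        r, _ = pearson_corr(x, y)
        _, _, r2 = linfit(x, y)
        assert r2 == pytest.approx(r**2, abs=1e-12)
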