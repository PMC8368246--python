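"""Cohort characterisation statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from mfiseg import CohortSpec, generate_cohort
from mfiseg.cohort import paired_group_tests, partial_corr, rm_ancova, sex_ancova


def _cohort_table(n=30, seed=0, **kwargs):
    return generate_cohort(CohortSpec(n_subjects=n, seed=seed, **kwargs))


class TestPairedGroupTests:
    def test_identical_columns_give_t0_p1(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                          "sex": "F", "age": 30.0, "bmi": 22.0})
        out = paired_group_tests(t, ["a", "b"])
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_constant_offset_zero_noise_flagged(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                          "sex": "F", "age": 30.0, "bmi": 22.0})
        out = paired_group_tests(t, ["a", "b"])
        assert out["flags"].iloc[0] == "zero_variance"
        assert math.isnan(out["p"].iloc[0])

    def test_matches_scipy_on_real_data(self):
        from scipy import stats

        table = _cohort_table(n=40, seed=3)
        out = paired_group_tests(table, ["MFSS", "TR"])
        t, p = stats.ttest_rel(table["MFSS"], table["TR"])
        assert out["t"].iloc[0] == pytest.approx(float(t))
        assert out["p"].iloc[0] == pytest.approx(float(p))

    def test_deep_exceeds_superficial_at_cohort_scale(self):
        # deep-group baselines are ~7-10 points above superficial ones, so
        # the paired contrast should be detected in nearly every replicate
        hits = 0
        for seed in range(10):
            table = _cohort_table(n=84, seed=seed)
            out = paired_group_tests(table, ["MFSS", "LS"])
            row = out.iloc[0]
            hits += int(row["mean_diff"] > 0 and row["p"] < 0.05)
        assert hits >= 9


class TestSexAncova:
    def test_small_table_matches_statsmodels(self):
        import statsmodels.api as sm

        table = _cohort_table(n=25, seed=5)
        res = sex_ancova(table, "MFSS")
        female = (table["sex"] == "F").astype(float)
        x = sm.add_constant(
            np.column_stack([female, table["age"], table["bmi"]])
        )
        fit = sm.OLS(table["MFSS"], x).fit()
        assert res.sex_effect == pytest.approx(fit.params.iloc[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse.iloc[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues.iloc[1], abs=1e-10)

    def test_recovers_injected_effect(self):
        table = _cohort_table(n=84, seed=1, sex_effect=1.8)
        res = sex_ancova(table, "SSCap")
        assert res.ci_low <= 1.8 <= res.ci_high

    def test_marginal_means_differ_by_effect(self):
        table = _cohort_table(n=60, seed=2)
        res = sex_ancova(table, "LC")
        assert res.emm_female - res.emm_male == pytest.approx(res.sex_effect)

    def test_single_sex_rejected(self):
        table = _cohort_table(n=20, seed=0)
        table["sex"] = "F"
        with pytest.raises(ValueError, match="both sexes"):
            sex_ancova(table, "MFSS")


class TestPartialCorr:
    def test_perfect_dependence(self, rng):
        x = rng.normal(size=30)
        controls = rng.normal(size=(30, 2))
        r, p = partial_corr(x, x, controls)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_no_controls_equals_plain_pearson(self, rng):
        from scipy import stats

        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        r, p = partial_corr(x, y)
        rr, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(float(rr), abs=1e-12)
        assert p == pytest.approx(float(pp), abs=1e-10)

    def test_hand_table_matches_two_stage_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0])
        c = np.column_stack(
            [np.array([1.0, 2, 3, 4, 5, 6, 7, 8]), np.array([2.0, 1, 2, 1, 2, 1, 2, 1])]
        )
        z = np.column_stack([np.ones(8), c])
        rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
        want = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
        r, _ = partial_corr(x, y, c)
        assert r == pytest.approx(want, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        d = pd.DataFrame(
            {
                "x": rng.normal(size=40),
                "c1": rng.normal(size=40),
                "c2": rng.normal(size=40),
            }
        )
        d["y"] = 0.5 * d.x + 0.3 * d.c1 + rng.normal(size=40)
        r, p = partial_corr(d.x, d.y, d[["c1", "c2"]].to_numpy())
        res = pg.partial_corr(d, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(res["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in res.columns else "p-val"
        assert p == pytest.approx(float(res[pcol].iloc[0]), abs=1e-8)

    def test_collinear_controls_rejected(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c1 = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_corr(x, y, np.column_stack([c1, 2 * c1]))

    def test_null_case_small_at_large_n(self):
        table = _cohort_table(
            n=500, seed=11, age_slope_deep=0.0, age_slope_superficial=0.0, bmi_slope=0.0
        )
        female = (table["sex"] == "F").to_numpy(float)
        r, _ = partial_corr(
            table["LC"], table["age"], np.column_stack([female, table["bmi"]])
        )
        assert abs(r) < 0.1


class TestRmAncova:
    def test_no_covariate_reduction_matches_pingouin_rm_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        n, g = 12, 4
        y = (
            10
            + rng.normal(0, 2, (n, 1))
            + np.array([0.0, 1.0, 2.0, 0.5])
            + rng.normal(0, 1, (n, g))
        )
        tab = pd.DataFrame(y, columns=list("ABCD"))
        res = rm_ancova(tab, list("ABCD"), between=(), covariates=())
        long = tab.reset_index().melt(
            id_vars="index", value_vars=list("ABCD"), var_name="g", value_name="v"
        )
        ref = pg.rm_anova(
            data=long, dv="v", within="g", subject="index", correction=True, detailed=True
        )
        assert res.f_group == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
        assert res.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), abs=1e-8)
        pcol = "p_GG_corr" if "p_GG_corr" in ref.columns else "p-GG-corr"
        assert res.p_group == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        n, g = 10, 5
        y = 5 + rng.normal(0, 3, (n, 1)) + rng.normal(0, 1, (n, g))
        tab = pd.DataFrame(y, columns=[f"g{i}" for i in range(g)])
        res = rm_ancova(tab, list(tab.columns), between=(), covariates=())
        assert res.gg_epsilon > 0.5  # compound symmetry keeps epsilon high

    def test_degrees_of_freedom_structure_at_cohort_scale(self):
        # 7 groups, n=84, between design {1, sex, age, bmi}: error df 80,
        # uncorrected within df (6, 480) scaled by epsilon
        table = _cohort_table(n=84, seed=4)
        res = rm_ancova(table)
        assert res.n == 84
        assert res.df2_sex == 80
        assert res.df1_group == pytest.approx(6 * res.gg_epsilon)
        assert res.df2_group == pytest.approx(6 * 80 * res.gg_epsilon)

    def test_detects_injected_group_differences(self):
        hits = 0
        for seed in range(10):
            table = _cohort_table(n=84, seed=seed)
            res = rm_ancova(table)
            hits += int(res.p_group < 0.05)
        assert hits >= 9

    def test_row_order_invariance(self):
        table = _cohort_table(n=30, seed=9)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rm_ancova(table)
        b = rm_ancova(shuffled)
        assert a.f_group == pytest.approx(b.f_group, abs=1e-10)
        assert a.f_sex == pytest.approx(b.f_sex, abs=1e-10)

    def test_sex_ancova_reduces_to_t_test_with_constant_covariates(self):
        # when age and BMI carry no information the sex ANCOVA F equals the
        # two-sample pooled-variance t squared
        from scipy import stats

        table = _cohort_table(n=40, seed=6)
        table["age"] = 30.0
        table["bmi"] = 22.0
        res = sex_ancova(table, "MFSS")
        f = table.loc[table["sex"] == "F", "MFSS"]
        m = table.loc[table["sex"] == "M", "MFSS"]
        t, p = stats.ttest_ind(f, m)
        assert res.f == pytest.approx(float(t) ** 2, rel=1e-10)
        assert res.p == pytest.approx(float(p), abs=1e-12)
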