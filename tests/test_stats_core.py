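"""t-vs-1, two-way ANOVA + Fisher LSD, and the Grubbs outlier test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coipquant.errors import (
    DegenerateSampleError,
    InvalidDesignError,
    InvalidInputError,
)
from coipquant.stats_core import (
    grubbs_critical,
    grubbs_outlier,
    lsd_pvalue,
    one_sample_t_vs_1,
    two_way_anova_lsd,
)


class TestTvs1:
    def test_reference_case(self):
        res = one_sample_t_vs_1([0.5, 0.6, 0.7])
        assert res.statistic == pytest.approx(-6.928203, abs=1e-5)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0202, abs=2e-4)
        # closed form: two-sided p from the t survival function
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(abs(res.statistic), 2), abs=1e-12
        )

    def test_sign_symmetry(self):
        a = one_sample_t_vs_1([0.5, 0.6, 0.7])
        b = one_sample_t_vs_1([1.5, 1.4, 1.3])  # deviations negated about 1
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p_value == pytest.approx(a.p_value)

    def test_zero_variance(self):
        with pytest.raises(DegenerateSampleError):
            one_sample_t_vs_1([1.0, 1.0, 1.0])

    def test_too_few(self):
        with pytest.raises(InvalidInputError):
            one_sample_t_vs_1([1.2])


def brute_force_balanced_anova(y, a, b):
    """Independent cell-means oracle for a balanced two-way design."""
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    n = len(df)
    levels_a, levels_b = sorted(df["a"].unique()), sorted(df["b"].unique())
    n_per_cell = n // (len(levels_a) * len(levels_b))
    mean_a = df.groupby("a")["y"].mean()
    mean_b = df.groupby("b")["y"].mean()
    mean_ab = df.groupby(["a", "b"])["y"].mean()
    ss_a = n_per_cell * len(levels_b) * sum((mean_a[la] - grand) ** 2 for la in levels_a)
    ss_b = n_per_cell * len(levels_a) * sum((mean_b[lb] - grand) ** 2 for lb in levels_b)
    ss_ab = n_per_cell * sum(
        (mean_ab[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
        for la in levels_a
        for lb in levels_b
    )
    ss_err = sum(
        (row["y"] - mean_ab[(row["a"], row["b"])]) ** 2 for _, row in df.iterrows()
    )
    return ss_a, ss_b, ss_ab, ss_err


def balanced_design(n_per_cell=8, seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for a in ("lo", "hi"):
        for b in ("ctrl", "trt"):
            mu = 1.0 + (a == "hi") * 0.5 + (b == "trt") * 0.3 + (a == "hi") * (b == "trt") * 0.4
            for _ in range(n_per_cell):
                rows.append({"a": a, "b": b, "y": mu + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_additive_design_zero_interaction(self):
        # cell means 1,2,3,4 with perfect additivity, n=2 per cell
        rows = []
        for a, b, mu in [("a1", "b1", 1.0), ("a1", "b2", 2.0), ("a2", "b1", 3.0), ("a2", "b2", 4.0)]:
            rows += [{"a": a, "b": b, "y": mu}] * 2
        df = pd.DataFrame(rows)
        res = two_way_anova_lsd(df["y"], df["a"], df["b"], names=("a", "b"))
        assert res.table.loc["a:b", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_partition_of_total_ss(self):
        df = balanced_design()
        res = two_way_anova_lsd(df["y"], df["a"], df["b"], names=("a", "b"))
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_cell_means_oracle(self):
        df = balanced_design(n_per_cell=8, seed=11)
        res = two_way_anova_lsd(df["y"], df["a"], df["b"], names=("a", "b"))
        ss_a, ss_b, ss_ab, ss_err = brute_force_balanced_anova(df["y"], df["a"], df["b"])
        assert res.table.loc["a", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert res.table.loc["b", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert res.table.loc["a:b", "sum_sq"] == pytest.approx(ss_ab, rel=1e-9)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(ss_err, rel=1e-9)

    def test_matches_statsmodels_on_unbalanced(self):
        """Independent cross-check of Type II SS under mild imbalance."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = balanced_design(n_per_cell=8, seed=5).iloc[:-2]  # drop 2 rows
        res = two_way_anova_lsd(df["y"], df["a"], df["b"], names=("a", "b"))
        fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
        sm_table = anova_lm(fit, typ=2)
        assert res.table.loc["a", "sum_sq"] == pytest.approx(
            sm_table.loc["C(a)", "sum_sq"], rel=1e-8
        )
        assert res.table.loc["b", "sum_sq"] == pytest.approx(
            sm_table.loc["C(b)", "sum_sq"], rel=1e-8
        )
        assert res.table.loc["a:b", "F"] == pytest.approx(
            sm_table.loc["C(a):C(b)", "F"], rel=1e-8
        )
        assert res.table.loc["a", "p"] == pytest.approx(
            sm_table.loc["C(a)", "PR(>F)"], rel=1e-8
        )

    def test_empty_cell_rejected(self):
        df = balanced_design()
        df = df[~((df["a"] == "hi") & (df["b"] == "trt"))]
        with pytest.raises(InvalidDesignError):
            two_way_anova_lsd(df["y"], df["a"], df["b"])

    def test_lsd_self_comparison_p_one(self):
        p, t = lsd_pvalue(0.7, 0.7, 8, 8, 0.05, 26)
        assert p == 1.0 and t == 0.0

    def test_lsd_table_shape_and_df(self):
        df = balanced_design()
        res = two_way_anova_lsd(df["y"], df["a"], df["b"], names=("a", "b"))
        assert len(res.lsd) == 6  # C(4,2) cell pairs
        assert (res.lsd["df"] == res.table.loc["Residual", "df"]).all()


class TestGrubbs:
    def test_flags_gross_outlier(self):
        res = grubbs_outlier([1.0, 1.0, 1.0, 10.0])
        assert res.statistic == pytest.approx(1.5)
        assert res.critical_value == pytest.approx(1.481, abs=2e-3)
        assert res.outlier_index == 3

    def test_no_outlier_in_symmetric_data(self):
        res = grubbs_outlier([0.9, 1.0, 1.1, 1.0, 0.95, 1.05])
        assert res.outlier_index is None

    def test_requires_three_values(self):
        with pytest.raises(InvalidInputError):
            grubbs_outlier([1.0, 2.0])

    def test_detection_rate_grows_with_magnitude(self):
        rng = np.random.default_rng(7)
        rates = []
        for magnitude in (2.0, 5.0, 20.0):
            hits = 0
            for _ in range(200):
                x = rng.normal(0, 1, 6)
                x[0] += magnitude
                if grubbs_outlier(x).outlier_index == 0:
                    hits += 1
            rates.append(hits / 200)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.99

    @pytest.mark.parametrize("n,expected", [(4, 1.481), (6, 1.887), (10, 2.290), (20, 2.709), (30, 2.908)])
    def test_published_critical_values(self, n, expected):
        assert grubbs_critical(n) == pytest.approx(expected, abs=1.5e-3)
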