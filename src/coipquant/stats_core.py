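"""Statistical procedures: one-sample t vs 1, two-way ANOVA + Fisher LSD, Grubbs.

These are the exact procedures the quantification pipeline reports:

* normalized ratios (lesion/intact, or condition/reference) are tested
  against the theoretical no-change value of 1 with a one-sample t-test;
* 2x2 co-IP designs (e.g. genotype x coactivator expression) are analyzed
  with a two-way ANOVA followed by uncorrected Fisher least-significant-
  difference pairwise comparisons using the pooled error term;
* single gross outliers in small ratio series are screened with a two-sided
  Grubbs test (one removal at most per invocation).

The ANOVA is computed from first principles via nested least-squares model
comparisons (Type II sums of squares, which coincide with the classical
balanced-design decomposition when cell sizes are equal); only the reference
distributions come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError, InvalidDesignError, InvalidInputError

__all__ = [
    "TestResult",
    "AnovaTable",
    "GrubbsResult",
    "one_sample_t_vs_1",
    "two_way_anova_lsd",
    "lsd_pvalue",
    "grubbs_critical",
    "grubbs_outlier",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


@dataclass
class AnovaTable:
    """Per-effect decomposition plus the uncorrected LSD pairwise table."""

    table: pd.DataFrame  # index: effect names + Residual; columns sum_sq, df, mean_sq, F, p
    lsd: pd.DataFrame  # pairwise cell comparisons
    ss_type: str
    cell_means: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class GrubbsResult:
    outlier_index: int | None
    statistic: float
    critical_value: float
    alpha: float = ALPHA_DEFAULT

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def one_sample_t_vs_1(
    values, target: float = 1.0, alpha: float = ALPHA_DEFAULT
) -> TestResult:
    """Two-sided one-sample t-test of a ratio series against a theoretical 1.

    t = (mean - target) / (sd / sqrt(n)) with df = n - 1.  A sample with zero
    variance carries no information about its own uncertainty and is rejected.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise InvalidInputError(f"need at least 2 values, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero sample variance; t statistic undefined")
    t = (x.mean() - target) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p), alpha=alpha)


# ---------------------------------------------------------------------------
# two-way ANOVA with Fisher's LSD


def _dummies(levels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level as baseline)."""
    cats = pd.Categorical(levels)
    codes = cats.codes
    k = len(cats.categories)
    out = np.zeros((len(levels), max(k - 1, 0)))
    for j in range(1, k):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _interaction(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    return np.column_stack(cols) if cols else np.empty((Xa.shape[0], 0))


def two_way_anova_lsd(
    values,
    factor_a,
    factor_b,
    alpha: float = ALPHA_DEFAULT,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Two-way factorial ANOVA with interaction, then uncorrected Fisher LSD.

    Sums of squares are Type II (each main effect adjusted for the other,
    the interaction adjusted for both), obtained by comparing residual sums
    of squares of nested least-squares fits; on balanced data this equals the
    classical cell-means decomposition exactly.  The LSD table compares every
    pair of cells with the pooled error mean square and error df, with no
    multiplicity correction.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Series(list(factor_a), name=names[0])
    b = pd.Series(list(factor_b), name=names[1])
    if not (len(y) == len(a) == len(b)):
        raise InvalidDesignError("values and factors must have equal length")
    if a.nunique() < 2 or b.nunique() < 2:
        raise InvalidDesignError("each factor needs at least 2 levels")
    cells = pd.DataFrame({"y": y, names[0]: a.values, names[1]: b.values})
    cell_sizes = cells.groupby([names[0], names[1]], observed=True)["y"].size()
    expected_cells = a.nunique() * b.nunique()
    if len(cell_sizes) < expected_cells or (cell_sizes < 1).any():
        raise InvalidDesignError("every factor-level combination needs data")

    ones = np.ones((len(y), 1))
    Xa, Xb = _dummies(a), _dummies(b)
    Xab = _interaction(Xa, Xb)

    rss_a = _rss(np.hstack([ones, Xa]), y)  # model with A only
    rss_b = _rss(np.hstack([ones, Xb]), y)
    rss_ab = _rss(np.hstack([ones, Xa, Xb]), y)  # both mains
    rss_full = _rss(np.hstack([ones, Xa, Xb, Xab]), y)

    df_a = a.nunique() - 1
    df_b = b.nunique() - 1
    df_ab = df_a * df_b
    df_err = len(y) - a.nunique() * b.nunique()
    if df_err < 1:
        raise InvalidDesignError("no residual degrees of freedom")

    ss_a = rss_b - rss_ab
    ss_b = rss_a - rss_ab
    ss_int = rss_ab - rss_full
    ss_err = rss_full
    mse = ss_err / df_err

    def row(ss, df):
        ms = ss / df
        F = ms / mse
        return {"sum_sq": ss, "df": df, "mean_sq": ms, "F": F, "p": float(stats.f.sf(F, df, df_err))}

    table = pd.DataFrame(
        {
            names[0]: row(ss_a, df_a),
            names[1]: row(ss_b, df_b),
            f"{names[0]}:{names[1]}": row(ss_int, df_ab),
            "Residual": {
                "sum_sq": ss_err,
                "df": df_err,
                "mean_sq": mse,
                "F": np.nan,
                "p": np.nan,
            },
        }
    ).T[["sum_sq", "df", "mean_sq", "F", "p"]]

    means = cells.groupby([names[0], names[1]], observed=True)["y"].agg(["mean", "size"])
    lsd_rows = []
    for (c1, c2) in combinations(means.index, 2):
        m1, n1 = means.loc[c1, "mean"], means.loc[c1, "size"]
        m2, n2 = means.loc[c2, "mean"], means.loc[c2, "size"]
        p, t = lsd_pvalue(m1, m2, n1, n2, mse, df_err)
        lsd_rows.append(
            {
                "cell_1": c1,
                "cell_2": c2,
                "mean_diff": m1 - m2,
                "t": t,
                "df": df_err,
                "p": p,
                "significant": p <= alpha,
            }
        )
    lsd = pd.DataFrame(lsd_rows)
    return AnovaTable(table=table, lsd=lsd, ss_type="II", cell_means=means)


def lsd_pvalue(
    mean_1: float,
    mean_2: float,
    n_1: int,
    n_2: int,
    mse: float,
    df_error: int,
) -> tuple[float, float]:
    """Fisher-LSD p-value and t statistic for one pair of cell means.

    Uses the pooled ANOVA error mean square; a comparison of a condition with
    itself (zero difference) gives t = 0 and p = 1.
    """
    if mse < 0 or n_1 < 1 or n_2 < 1 or df_error < 1:
        raise InvalidInputError("invalid LSD inputs")
    se = np.sqrt(mse * (1.0 / n_1 + 1.0 / n_2))
    if se == 0:
        if mean_1 == mean_2:
            return 1.0, 0.0
        raise DegenerateSampleError("zero pooled error with unequal means")
    t = (mean_1 - mean_2) / se
    return float(2.0 * stats.t.sf(abs(t), df_error)), float(t)


# ---------------------------------------------------------------------------
# Grubbs single-outlier test


def grubbs_critical(n: int, alpha: float = ALPHA_DEFAULT) -> float:
    """Two-sided Grubbs critical value from the t-based closed form.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_(1 - alpha/(2n), n-2).
    """
    if n < 3:
        raise InvalidInputError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_outlier(values, alpha: float = ALPHA_DEFAULT) -> GrubbsResult:
    """Single-pass, two-sided Grubbs test for one gross outlier.

    G = max |x - mean| / sd (sample sd, ddof 1).  At most one point is
    flagged per invocation — the screening protocol removes at most one
    outlier per ratio series.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InvalidInputError("Grubbs test requires n >= 3")
    if np.isnan(x).any():
        raise InvalidInputError("NaN in Grubbs input")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(None, 0.0, grubbs_critical(x.size, alpha), alpha)
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    G = float(dev[idx] / sd)
    crit = grubbs_critical(x.size, alpha)
    return GrubbsResult(idx if G > crit else None, G, crit, alpha)
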