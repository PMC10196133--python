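"""The cohort statistics layer.

* ROUT outlier screening (Motulsky–Brown reduced to a constant model) before
  group comparisons.
* Two-way fixed-effects genotype×age ANOVA with interaction; Type-III-style
  sums of squares with sum-to-zero contrasts, so unbalanced cells (group
  sizes 9–29) are handled the way mainstream commercial software does.
* Sidak-adjusted per-age genotype comparisons using the pooled residual
  variance of the two-way model.
* Deming (errors-in-variables) regression and Spearman rank correlation for
  structure–function association where both axes carry measurement error.
* Percent-relative summaries against a reference cohort with a t-based 95%
  confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import InvalidParameterError


# ---------------------------------------------------------------------------
# ROUT outlier screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierScreen:
    q: float                     # FDR coefficient Q, percent
    mask: np.ndarray             # True = keep, False = flagged outlier
    robust_center: float
    rsdr: float                  # robust SD of residuals

    @property
    def n_flagged(self) -> int:
        return int(np.sum(~self.mask))


def rout_outliers(values: Sequence[float], q: float = 1.0) -> OutlierScreen:
    """Flag outliers in one group of measurements at FDR coefficient ``q`` (%).

    The regression-based procedure reduces, for a single group, to a constant
    model: the robust centre is the median, and the robust SD of residuals
    (RSDR) is the 68.27th percentile of the absolute residuals with the
    small-sample correction ``n/(n-1)``. Each point's two-tailed p-value from
    ``t = |residual|/RSDR`` on ``n-1`` df is then screened with the
    Benjamini–Hochberg step-up rule at rate ``q/100``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidParameterError("ROUT needs at least 3 values")
    if not 0 < q < 100:
        raise InvalidParameterError("Q must be in (0, 100) percent")
    center = float(np.median(v))
    resid = v - center
    abs_resid = np.abs(resid)
    n = v.size
    rsdr = float(np.percentile(abs_resid, 68.27) * n / (n - 1))
    mask = np.ones(n, dtype=bool)
    if rsdr == 0.0:  # zero spread: nothing can be an outlier
        return OutlierScreen(q=q, mask=mask, robust_center=center, rsdr=0.0)
    t = abs_resid / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p)
    thresholds = (q / 100.0) * (np.arange(1, n + 1) / n)
    below = p[order] <= thresholds
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1
        mask[order[:k]] = False
    return OutlierScreen(q=q, mask=mask, robust_center=center, rsdr=rsdr)


# ---------------------------------------------------------------------------
# two-way ANOVA + Sidak
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    """Genotype×age ANOVA. ``table`` is indexed by factor name
    (genotype, age, interaction, residual) with columns ss, df, F, p."""

    table: pd.DataFrame
    n: int
    degenerate: bool = False  # zero residual variance with group differences

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def f(self, factor: str) -> float:
        return float(self.table.loc[factor, "F"])


def _anova_frame(values, genotype, age) -> pd.DataFrame:
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "genotype": pd.Categorical(genotype),
        "age": pd.Categorical(age),
    })
    if df["genotype"].nunique() < 2 or df["age"].nunique() < 2:
        raise InvalidParameterError("each factor needs at least 2 levels")
    counts = df.groupby(["genotype", "age"], observed=False).size()
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        raise InvalidParameterError(
            f"empty design cell genotype={cell[0]!r}, age={cell[1]!r}")
    return df


def two_way_anova(values: Sequence[float], genotype: Sequence,
                  age: Sequence) -> AnovaTable:
    """Fixed-effects genotype×age ANOVA with interaction.

    Sum-to-zero contrasts with Type-III sums of squares; for balanced designs
    this coincides with the textbook decomposition. Zero residual variance
    with unequal cell means is reported as F=inf, p=0 with the ``degenerate``
    flag set.
    """
    df = _anova_frame(values, genotype, age)
    model = smf.ols("value ~ C(genotype, Sum) * C(age, Sum)", data=df).fit()
    n = len(df)
    ss_resid = float(model.ssr)
    df_resid = float(model.df_resid)
    name_map = {
        "C(genotype, Sum)": "genotype",
        "C(age, Sum)": "age",
        "C(genotype, Sum):C(age, Sum)": "interaction",
        "Residual": "residual",
    }
    degenerate = False
    cell_means = df.groupby(["genotype", "age"], observed=True)["value"].mean()
    if ss_resid <= 1e-12 * max(float(np.var(df["value"])) * n, 1.0):
        rows = {}
        grand = float(df["value"].mean())
        effect_ss = float(np.sum((cell_means - grand) ** 2))
        degenerate = effect_ss > 0
        with np.errstate(divide="ignore"):
            raw = anova_lm(model, typ=3)
        for src, label in name_map.items():
            if src == "Residual":
                rows[label] = (ss_resid, df_resid, np.nan, np.nan)
            else:
                ss = float(raw.loc[src, "sum_sq"])
                dof = float(raw.loc[src, "df"])
                big = ss > 1e-12 * max(abs(grand), 1.0)
                rows[label] = (ss, dof, np.inf if big else 0.0,
                               0.0 if big else 1.0)
        table = pd.DataFrame.from_dict(
            rows, orient="index", columns=["ss", "df", "F", "p"])
        return AnovaTable(table=table, n=n, degenerate=degenerate)
    raw = anova_lm(model, typ=3)
    raw = raw.rename(index=name_map).loc[list(name_map.values())]
    table = pd.DataFrame({
        "ss": raw["sum_sq"], "df": raw["df"], "F": raw["F"], "p": raw["PR(>F)"],
    })
    return AnovaTable(table=table, n=n, degenerate=degenerate)


def sidak_adjust(p_raw: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiplicity adjustment ``p_adj = 1 - (1 - p)^m``, clipped to [0,1]."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("raw p-values must lie in [0, 1]")
    adj = np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)
    return float(adj) if np.isscalar(p_raw) else adj


def sidak_alpha(alpha: float, m: int) -> float:
    """Per-comparison threshold keeping family-wise error at ``alpha``."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


@dataclass(frozen=True)
class SidakComparisons:
    """Per-age WT-vs-HOM contrasts with Sidak-adjusted p-values.

    ``table`` indexed by age: difference (group1 - group2), se, t, p_raw,
    p_adj; ``m`` is the number of comparisons (ages)."""

    table: pd.DataFrame
    m: int
    group_pair: tuple[str, str]


def sidak_comparisons(values: Sequence[float], genotype: Sequence,
                      age: Sequence,
                      group_pair: tuple[str, str] = ("WT", "HOM"),
                      ) -> SidakComparisons:
    """Within each age, compare the two genotypes using the pooled residual
    mean square of the two-way model, Sidak-adjusted over the ages."""
    df = _anova_frame(values, genotype, age)
    model = smf.ols("value ~ C(genotype, Sum) * C(age, Sum)", data=df).fit()
    mse = model.ssr / model.df_resid if model.df_resid > 0 else np.nan
    ages = sorted(df["age"].unique())
    m = len(ages)
    rows = {}
    for a in ages:
        sub = df[df["age"] == a]
        g1 = sub[sub["genotype"] == group_pair[0]]["value"]
        g2 = sub[sub["genotype"] == group_pair[1]]["value"]
        diff = float(g1.mean() - g2.mean())
        se = float(np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2))))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p_raw = float(2.0 * sps.t.sf(abs(t), df=model.df_resid))
        rows[a] = (diff, se, t, p_raw, sidak_adjust(p_raw, m))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["difference", "se", "t", "p_raw", "p_adj"])
    return SidakComparisons(table=table, m=m, group_pair=group_pair)


# ---------------------------------------------------------------------------
# association: Deming + Spearman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    lam: float  # error-variance ratio Var(err_y)/Var(err_x)


def deming_fit(x: Sequence[float], y: Sequence[float],
               lam: float = 1.0) -> DemingFit:
    """Errors-in-variables straight line.

    ``lam`` is the ratio of the y-error variance to the x-error variance;
    ``lam = 1`` is orthogonal (total least squares) regression. The closed
    form minimizes the lambda-weighted orthogonal residuals::

        slope = (s_yy - lam*s_xx + sqrt((s_yy - lam*s_xx)^2 + 4*lam*s_xy^2))
                / (2 * s_xy)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need n >= 3 paired observations")
    if lam <= 0:
        raise InvalidParameterError("lambda must be > 0")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    if sxx == 0 and syy == 0:
        raise InvalidParameterError("zero variance in both x and y")
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0:
        raise InvalidParameterError(
            "zero covariance: the Deming slope is undefined")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return DemingFit(slope=float(slope), intercept=intercept, lam=lam)


@dataclass(frozen=True)
class SpearmanResult:
    rs: float
    p: float
    n: int
    method: str  # "asymptotic" | "permutation"


def spearman(x: Sequence[float], y: Sequence[float],
             method: str = "asymptotic",
             n_permutations: int = 10000,
             seed: int | None = None) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    ``method="asymptotic"`` uses the t-approximation; ``"permutation"``
    permutes ``y`` with an explicit seed and reports the two-sided
    permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need n >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InvalidParameterError("Spearman undefined for constant input")
    rs, p = sps.spearmanr(x, y)
    if method == "asymptotic":
        return SpearmanResult(rs=float(rs), p=float(p), n=x.size,
                              method="asymptotic")
    if method != "permutation":
        raise InvalidParameterError(f"unknown method {method!r}")
    if seed is None:
        raise InvalidParameterError("permutation method requires a seed")
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_permutations):
        hits += abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= observed - 1e-12
    p_perm = (hits + 1) / (n_permutations + 1)
    return SpearmanResult(rs=float(rs), p=float(p_perm), n=x.size,
                          method="permutation")


# ---------------------------------------------------------------------------
# percent-relative summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentRelative:
    percent: np.ndarray        # each value as % of reference mean
    reference_mean: float
    reference_ci: tuple[float, float]  # 95% CI of the reference mean, in %
    sem_percent: float         # SEM of `percent`


def percent_relative_summary(values: Sequence[float],
                             reference_values: Sequence[float],
                             confidence: float = 0.95) -> PercentRelative:
    """Scale values to the reference-group mean (=100%).

    The reference band is the t-interval ``mean ± t(1-(1-c)/2, n-1)·SEM``
    expressed on the percent scale — the shaded band plotted behind
    percent-change panels.
    """
    values = np.asarray(values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise InvalidParameterError("reference group is empty")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise InvalidParameterError(
            "reference mean is zero; use the densitometry fallback rule")
    percent = 100.0 * values / ref_mean
    if ref.size > 1:
        sem = float(ref.std(ddof=1) / np.sqrt(ref.size))
        half = sps.t.ppf(1.0 - (1.0 - confidence) / 2.0, df=ref.size - 1) * sem
    else:
        half = np.inf
    ci = (100.0 * (ref_mean - half) / ref_mean, 100.0 * (ref_mean + half) / ref_mean)
    sem_pct = (float(percent.std(ddof=1) / np.sqrt(percent.size))
               if percent.size > 1 else float("nan"))
    return PercentRelative(percent=percent, reference_mean=ref_mean,
                           reference_ci=ci, sem_percent=sem_pct)
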