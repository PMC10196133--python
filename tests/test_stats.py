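"""Statistics layer vs independent oracles: direct sums of squares, explicit
rank arithmetic, eigen-decomposition regression, closed-form Sidak, and an
explicit-loop outlier reference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from retinerg import stats as st
from retinerg.errors import InvalidParameterError


# ---------------------------------------------------------------------------
# independent oracles (deliberately written without reusing the implementation)
# ---------------------------------------------------------------------------

def rout_reference(values, q):
    """Explicit-loop constant-model outlier screen: median centre, RSDR from
    the 68.27th percentile with n/(n-1) correction, t-based p-values screened
    step-up at FDR rate q."""
    values = list(map(float, values))
    n = len(values)
    med = sorted(values)[n // 2] if n % 2 else sum(sorted(values)[n // 2 - 1:
                                                                  n // 2 + 1]) / 2
    abs_resid = [abs(v - med) for v in values]
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0:
        return set()
    pvals = [(2 * sps.t.sf(ar / rsdr, df=n - 1), i)
             for i, ar in enumerate(abs_resid)]
    pvals.sort()
    flagged = set()
    k = 0
    for rank, (p, _) in enumerate(pvals, start=1):
        if p <= (q / 100.0) * rank / n:
            k = rank
    for p, i in pvals[:k]:
        flagged.add(i)
    return flagged


def midranks(values):
    """Counting-based mid-ranks (1-based, ties averaged)."""
    return [1.0 + sum(1 for u in values if u < x)
            + (sum(1 for u in values if u == x) - 1) / 2.0 for x in values]


def balanced_anova_oracle(values, genotype, age):
    """Textbook two-way ANOVA sums of squares for a balanced design."""
    import pandas as pd
    df = pd.DataFrame({"v": values, "g": genotype, "a": age})
    grand = df["v"].mean()
    n = len(df)
    n_per_cell = n / (df["g"].nunique() * df["a"].nunique())
    ss_total = ((df["v"] - grand) ** 2).sum()
    ss_g = sum(len(sub) * (sub["v"].mean() - grand) ** 2
               for _, sub in df.groupby("g"))
    ss_a = sum(len(sub) * (sub["v"].mean() - grand) ** 2
               for _, sub in df.groupby("a"))
    ss_cells = sum(len(sub) * (sub["v"].mean() - grand) ** 2
                   for _, sub in df.groupby(["g", "a"]))
    ss_int = ss_cells - ss_g - ss_a
    ss_res = ss_total - ss_cells
    df_g = df["g"].nunique() - 1
    df_a = df["a"].nunique() - 1
    df_int = df_g * df_a
    df_res = n - df["g"].nunique() * df["a"].nunique()
    out = {}
    for name, ss, dof in [("genotype", ss_g, df_g), ("age", ss_a, df_a),
                          ("interaction", ss_int, df_int)]:
        f = (ss / dof) / (ss_res / df_res)
        out[name] = (ss, dof, f, sps.f.sf(f, dof, df_res))
    out["residual"] = (ss_res, df_res, np.nan, np.nan)
    return out


# ---------------------------------------------------------------------------
# ROUT
# ---------------------------------------------------------------------------

class TestRout:
    def test_identical_values_no_outliers(self):
        screen = st.rout_outliers([5.0] * 10)
        assert screen.n_flagged == 0 and screen.rsdr == 0.0

    def test_planted_outlier_flagged_and_matches_reference(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.standard_normal(20), [10.0]])
        screen = st.rout_outliers(values, q=1.0)
        flagged = set(np.nonzero(~screen.mask)[0])
        assert flagged == {20}
        assert flagged == rout_reference(values, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(15)
        if seed % 2:
            values[0] += rng.choice([6.0, -8.0])
        screen = st.rout_outliers(values, q=1.0)
        assert set(np.nonzero(~screen.mask)[0]) == rout_reference(values, 1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.rout_outliers([1.0, 2.0])


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

class TestTwoWayAnova:
    def _balanced(self, seed=0, n_per_cell=4, effect=0.0):
        rng = np.random.default_rng(seed)
        values, genotype, age = [], [], []
        for g in ("WT", "HOM"):
            for a in (4, 6, 14):
                for _ in range(n_per_cell):
                    v = rng.standard_normal() + (effect if g == "HOM" else 0.0)
                    values.append(v)
                    genotype.append(g)
                    age.append(a)
        return np.array(values), genotype, age

    def test_balanced_matches_direct_sums_of_squares(self):
        values, genotype, age = self._balanced(seed=3, effect=1.0)
        table = st.two_way_anova(values, genotype, age).table
        oracle = balanced_anova_oracle(values, genotype, age)
        for factor in ("genotype", "age", "interaction"):
            ss, dof, f, p = oracle[factor]
            assert table.loc[factor, "ss"] == pytest.approx(ss, rel=1e-10)
            assert table.loc[factor, "df"] == dof
            assert table.loc[factor, "F"] == pytest.approx(f, rel=1e-10)
            assert table.loc[factor, "p"] == pytest.approx(p, rel=1e-10)

    def test_ss_additivity_and_df_sum_balanced(self):
        values, genotype, age = self._balanced(seed=5, effect=0.5)
        result = st.two_way_anova(values, genotype, age)
        ss_total = float(np.sum((values - values.mean()) ** 2))
        assert result.table["ss"].sum() == pytest.approx(ss_total, rel=1e-9)
        assert result.table["df"].sum() == len(values) - 1

    def test_pure_genotype_shift_zeroes_age_terms(self):
        # noise-free construction: only a genotype offset
        values, genotype, age = [], [], []
        for g in ("WT", "HOM"):
            for a in (4, 6, 14):
                for _ in range(3):
                    values.append(10.0 + (2.0 if g == "HOM" else 0.0))
                    genotype.append(g)
                    age.append(a)
        result = st.two_way_anova(values, genotype, age)
        assert result.f("age") == 0.0
        assert result.f("interaction") == 0.0
        # zero residual variance with a real genotype difference
        assert result.degenerate
        assert result.f("genotype") == np.inf
        assert result.p("genotype") == 0.0

    def test_empty_cell_named(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        genotype = ["WT", "WT", "WT", "HOM", "HOM"]
        age = [4, 6, 6, 4, 4]  # no HOM at age 6
        with pytest.raises(InvalidParameterError, match="HOM"):
            st.two_way_anova(values, genotype, age)

    def test_unbalanced_design_runs(self):
        rng = np.random.default_rng(11)
        sizes = {("WT", 4): 9, ("WT", 6): 18, ("WT", 14): 29,
                 ("HOM", 4): 12, ("HOM", 6): 15, ("HOM", 14): 23}
        values, genotype, age = [], [], []
        for (g, a), n in sizes.items():
            for _ in range(n):
                values.append(rng.standard_normal() + (1.0 if g == "HOM" else 0))
                genotype.append(g)
                age.append(a)
        result = st.two_way_anova(values, genotype, age)
        assert result.p("genotype") < 0.001
        assert result.table["df"].sum() == len(values) - 1


# ---------------------------------------------------------------------------
# Sidak
# ---------------------------------------------------------------------------

class TestSidak:
    def test_single_comparison_unchanged(self):
        assert st.sidak_adjust(0.03, 1) == pytest.approx(0.03, abs=1e-15)

    def test_closed_form_values(self):
        assert st.sidak_adjust(0.01, 5) == pytest.approx(0.049010, abs=1e-6)
        assert st.sidak_alpha(0.05, 3) == pytest.approx(0.016952, abs=1e-6)

    @settings(deadline=None, max_examples=100)
    @given(p=hst.floats(0.0, 1.0), m=hst.integers(1, 50))
    def test_adjusted_at_least_raw_and_monotone_in_m(self, p, m):
        adj = st.sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-15
        assert st.sidak_adjust(p, m + 1) >= adj - 1e-15

    def test_invalid_m_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.sidak_adjust(0.05, 0)

    def test_per_age_comparisons(self):
        rng = np.random.default_rng(2)
        values, genotype, age = [], [], []
        for g in ("WT", "HOM"):
            for a in (4, 6, 14):
                for _ in range(10):
                    values.append(rng.standard_normal()
                                  + (3.0 if (g, a) == ("HOM", 14) else 0.0))
                    genotype.append(g)
                    age.append(a)
        comp = st.sidak_comparisons(values, genotype, age)
        assert comp.m == 3
        assert (comp.table["p_adj"] >= comp.table["p_raw"] - 1e-15).all()
        assert comp.table.loc[14, "p_adj"] < 0.001
        assert comp.table.loc[4, "p_adj"] > 0.05


# ---------------------------------------------------------------------------
# Deming regression
# ---------------------------------------------------------------------------

class TestDeming:
    @pytest.mark.parametrize("lam", [0.25, 1.0, 4.0])
    def test_exact_line_recovered_for_any_lambda(self, lam):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = st.deming_fit(x, 2.0 * x + 1.0, lam=lam)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_slope_matches_eigen_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 2, 60)
        y = 1.5 * x + rng.normal(0, 1, 60)
        fit = st.deming_fit(x, y, lam=1.0)
        # principal axis of the centred covariance matrix
        cov = np.cov(np.vstack([x, y]), ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        principal = evecs[:, np.argmax(evals)]
        assert fit.slope == pytest.approx(principal[1] / principal[0],
                                          rel=1e-10)

    def test_swap_symmetry_at_lambda_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = 0.7 * x + rng.normal(0, 0.5, 40)
        ab = st.deming_fit(x, y, lam=1.0)
        ba = st.deming_fit(y, x, lam=1.0)
        assert ba.slope == pytest.approx(1.0 / ab.slope, rel=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.deming_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

SPEARMAN_SUITE = [
    (1, 2, 3), (3, 2, 1), (1, 1, 2), (2, 1, 1, 2),
    (1, 2, 2, 3, 3, 3), (5, 1, 4, 1, 5), (1, 2, 3, 4, 5, 6, 7, 8),
    (2, 2, 2, 1, 3), (1, 3, 2, 4, 3, 5, 4, 6),
]


class TestSpearman:
    def test_strictly_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert st.spearman(x, [2.0, 5.0, 9.0, 11.0]).rs == pytest.approx(1.0)
        assert st.spearman(x, [11.0, 9.0, 5.0, 2.0]).rs == pytest.approx(-1.0)

    @pytest.mark.parametrize("ys", SPEARMAN_SUITE)
    def test_equals_brute_force_midrank_pearson(self, ys):
        # oracle: counting-based mid-ranks + plain Pearson on the ranks
        rng = np.random.default_rng(hash(ys) % 2 ** 31)
        for _ in range(4):
            xs = tuple(rng.integers(0, 4, size=len(ys)).tolist())
            if len(set(xs)) == 1:
                continue
            expected = np.corrcoef(midranks(xs), midranks(ys))[0, 1]
            assert st.spearman(xs, ys).rs == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_p_reproducible(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        a = st.spearman(x, y, method="permutation", n_permutations=500, seed=9)
        b = st.spearman(x, y, method="permutation", n_permutations=500, seed=9)
        assert a.p == b.p
        assert 0.0 < a.p <= 1.0


# ---------------------------------------------------------------------------
# percent-relative summaries
# ---------------------------------------------------------------------------

class TestPercentRelative:
    def test_reference_vs_itself_is_100(self):
        ref = [10.0, 12.0, 8.0, 10.0]
        out = st.percent_relative_summary(ref, ref)
        assert out.percent.mean() == pytest.approx(100.0, abs=1e-12)

    def test_ci_half_width_closed_form(self):
        ref = np.array([10.0, 12.0, 8.0, 10.0])
        out = st.percent_relative_summary(ref, ref)
        sem = ref.std(ddof=1) / 2.0
        half = sps.t.ppf(0.975, df=3) * sem
        expected_high = 100.0 * (ref.mean() + half) / ref.mean()
        assert out.reference_ci[1] == pytest.approx(expected_high, rel=1e-12)
        assert out.reference_ci[0] == pytest.approx(200.0 - expected_high,
                                                    rel=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.percent_relative_summary([1.0], [])
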