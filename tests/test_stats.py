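"""Statistical engine vs enumeration oracles and an external reference."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from simscore import build_correlations, build_table1, compare_groups, correlate, sims_by_glyco
from simscore.errors import DomainError
from simscore.stats import (
    GLYCO_DISPLAY,
    chi_square,
    fisher_exact_2xk,
    mann_whitney,
    t_test,
)


def _mw_exact_oracle(x, y):
    """Full enumeration of all C(n+m, n) group labelings of the pooled sample:
    two-sided p = 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = set(idx)
        a = [pooled[i] for i in grp]
        b = [pooled[i] for i in range(len(pooled)) if i not in grp]
        us.append(sum(1 for xi in a for yj in b if xi > yj))
    us = np.array(us, dtype=float)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_textbook_separation(self):
        stat, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(77)
        for n in range(1, 9):
            for m in range(1, 11 - n):
                x = rng.normal(size=n)
                y = rng.normal(loc=0.5, size=m)
                _, p = mann_whitney(x, y)
                assert p == pytest.approx(_mw_exact_oracle(x, y), abs=1e-12), (n, m)

    def test_identical_groups(self):
        stat, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_tie_correction_used_for_large_tied_samples(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(1, 6, 45).astype(float)
        _, p = mann_whitney(x, y)
        assert 0.0 <= p <= 1.0


class TestTTest:
    def test_identical_constant_groups_degenerate(self):
        stat, p = t_test([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        stat, p = t_test([5, 5, 5], [5, 5, 5])
        assert (stat, p) == (0.0, 1.0)

    def test_pooled_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0])
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        stat, _ = t_test(x, y)
        assert stat == pytest.approx(t_hand, rel=1e-12)

    def test_welch_flag_changes_statistic(self):
        x = [1.0, 2.0, 3.0, 4.0, 10.0]
        y = [2.0, 2.1, 2.2]
        assert t_test(x, y, welch=True)[1] != t_test(x, y, welch=False)[1]


class TestFisherExact:
    def test_perfect_separation_2x2(self):
        # only the two extreme tables attain the observed probability:
        # p = 2 / C(20, 10)
        _, p = fisher_exact_2xk(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_agrees_with_scipy_on_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(5)
        for _ in range(20):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum() == 0:
                continue
            _, p_mine = fisher_exact_2xk(table)
            _, p_scipy = fisher_exact(table)
            assert p_mine == pytest.approx(p_scipy, rel=1e-9), table

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_2x4_agrees_with_r_reference(self):
        table = [[155, 4, 8, 0], [258, 4, 5, 16]]
        _, p_mine = fisher_exact_2xk(np.array(table))
        r_code = (
            "cat(fisher.test(matrix(c(155,258,4,4,8,5,0,16), nrow=2))$p.value)"
        )
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, check=True)
        p_r = float(out.stdout.strip())
        assert p_mine == pytest.approx(p_r, rel=1e-6)

    def test_empty_columns_dropped(self):
        _, p_with = fisher_exact_2xk(np.array([[3, 0, 5], [2, 0, 4]]))
        _, p_without = fisher_exact_2xk(np.array([[3, 5], [2, 4]]))
        assert p_with == pytest.approx(p_without, rel=1e-12)


def test_chi_square_no_continuity_correction_by_default():
    table = np.array([[20, 30], [35, 15]])
    stat, _ = chi_square(table)
    from scipy.stats import chi2_contingency

    assert stat == pytest.approx(chi2_contingency(table, correction=False).statistic)


class TestCorrelate:
    def _df(self, x, y):
        return pd.DataFrame({"sims": x, "y": y})

    def test_perfect_linear_relation(self):
        df = self._df([1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0, 9.0])
        row = correlate(df, "y", "pearson")
        assert row.r == pytest.approx(1.0)
        assert row.n_used == 4

    def test_three_point_hand_computation(self):
        df = self._df([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert correlate(df, "y", "pearson").r == pytest.approx(0.5)
        assert correlate(df, "y", "spearman").r == pytest.approx(0.5)

    def test_null_correlation_bounded(self):
        rng = np.random.default_rng(17)
        df = self._df(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(correlate(df, "y", "pearson").r) < 0.05

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.5, size=50)
        base = correlate(self._df(x, y), "y", "pearson").r
        assert correlate(self._df(x, 3 * y + 7), "y", "pearson").r == pytest.approx(base)
        assert correlate(self._df(x, -2 * y), "y", "pearson").r == pytest.approx(-base)

    def test_spearman_invariant_under_monotone_map(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=60)
        y = x + rng.normal(scale=1.0, size=60)
        base = correlate(self._df(x, y), "y", "spearman").r
        assert correlate(self._df(x, np.exp(y)), "y", "spearman").r == pytest.approx(base)

    def test_zero_variance_is_undefined_not_a_number(self):
        row = correlate(self._df([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]), "y", "pearson")
        assert row.r is None and row.p_value is None

    def test_listwise_deletion_recorded(self):
        df = self._df([1.0, 2.0, 3.0, 4.0], [1.0, np.nan, 2.0, 5.0])
        assert correlate(df, "y", "pearson").n_used == 3

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            correlate(self._df([1.0, 2.0], [1.0, 2.0]), "y", "pearson")


class TestCompareGroups:
    def test_group_swap_symmetry(self, scored_cohort):
        row = compare_groups(scored_cohort, "age_group", "sims", "t_test")
        flipped = scored_cohort.copy()
        flipped["age_group"] = flipped["age_group"].map(
            {"young": "a_young", "older": "b_older"})
        row2 = compare_groups(flipped, "age_group", "sims", "t_test")
        # young listed first in both orderings -> same |stat|, same p
        assert row2.p_value == pytest.approx(row.p_value)
        assert abs(row2.statistic) == pytest.approx(abs(row.statistic))

    def test_empty_group_rejected(self, scored_cohort):
        df = scored_cohort.copy()
        df.loc[df["age_group"] == "young", "pai1"] = np.nan
        with pytest.raises(DomainError):
            compare_groups(df, "age_group", "pai1", "t_test")

    def test_proportion_summary(self, scored_cohort):
        row = compare_groups(scored_cohort, "age_group", "obesity_label",
                             "chi_square", level="obese")
        assert "%" in row.summary1
        assert 0 <= row.p_value <= 1


class TestTable1:
    def test_variable_test_assignments(self, scored_cohort):
        rows = {r.variable: r for r in build_table1(scored_cohort)}
        assert rows["sims"].test == "t_test"
        assert rows["triglycerides"].test == "mann_whitney"
        assert rows["glyco_label"].test == "fisher_exact"
        assert rows["obesity_label"].test == "chi_square"
        assert all(0 <= r.p_value <= 1 for r in rows.values()
                   if r.p_value is not None)

    def test_summary_formats(self, scored_cohort):
        rows = {r.variable: r for r in build_table1(scored_cohort)}
        assert "±" in rows["waist"].summary1
        assert "(" in rows["triglycerides"].summary1

    def test_single_group_cohort_rejected(self, scored_cohort):
        young_only = scored_cohort[scored_cohort["age_group"] == "young"]
        with pytest.raises(DomainError):
            build_table1(young_only)

    def test_unknown_variable_skipped_with_warning(self, scored_cohort, caplog):
        df = scored_cohort.drop(columns=["pai1"])
        with caplog.at_level("WARNING"):
            rows = build_table1(df)
        assert "pai1" not in {r.variable for r in rows}
        assert any("pai1" in rec.message for rec in caplog.records)


class TestSimsByGlyco:
    def test_display_ordering_and_groups(self, scored_cohort):
        t2 = sims_by_glyco(scored_cohort)
        assert set(t2["group"]) <= {"total", "young", "older"}
        valid = {d for _, d in GLYCO_DISPLAY}
        assert set(t2["display"]) <= valid

    def test_single_member_category_has_no_sd(self, scored_cohort):
        df = scored_cohort.copy()
        df["glyco_label"] = "normal"
        df.loc[df.index[:1], "glyco_label"] = "dm"
        t2 = sims_by_glyco(df.assign(age_group="older"))
        dm_row = t2[(t2["group"] == "total") & (t2["glyco_label"] == "dm")]
        assert len(dm_row) == 1
        assert np.isnan(dm_row["sims_sd"].iloc[0])

    def test_unscored_cohort_rejected(self):
        with pytest.raises(DomainError):
            sims_by_glyco(pd.DataFrame({"x": [1.0]}))


def test_correlation_screen_shape(scored_cohort):
    rows = build_correlations(scored_cohort)
    groups = {r.group for r in rows}
    assert {"total", "young", "older"} <= groups
    assert all(-1 <= r.r <= 1 for r in rows if r.r is not None)
    assert all(r.n_used >= 3 for r in rows)


def test_t_test_type_i_error_calibrated():
    """Under a normal null (n=50 per arm), the pooled t test should reject at
    about the nominal 5% rate."""
    rng = np.random.default_rng(2024)
    reps = 2_000
    x = rng.normal(size=(reps, 50))
    y = rng.normal(size=(reps, 50))
    from scipy.stats import ttest_ind

    p = ttest_ind(x, y, axis=1).pvalue
    rate = float(np.mean(p < 0.05))
    assert 0.04 <= rate <= 0.06
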