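"""Group comparisons and correlation screening.

Reproduces the analysis surface of a baseline-characteristics table: each
variable is compared between the two age groups with the test matching its
scale (pooled-variance t test for mean ± SD rows, Mann-Whitney U for
median (Q1–Q3) rows, chi-square for the obesity proportion, 2×k
Fisher-Freeman-Halton exact test for the glycoregulation distribution), plus
a correlation screen of the siMS score against every biomarker (Pearson or
Spearman per a declarative variable→method map) and siMS summaries per
glycoregulation category.

The variable→test and variable→method maps ship as package data
(``table_layout.yaml``) so the reporting surface is configurable without
touching code. Listwise deletion per analysis; raw p-values by default with
an optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.special import gammaln

from .errors import DomainError

logger = logging.getLogger(__name__)

TESTS = ("t_test", "mann_whitney", "chi_square", "fisher_exact")
EXACT_MW_MAX = 8  # exact Mann-Whitney null when min(n, m) <= this and no ties

#: display order / names for glycoregulation categories
GLYCO_DISPLAY = (("normal", "No"), ("ifg", "IFG"), ("igt", "IGT"), ("dm", "DM"))


@dataclass
class ComparisonRow:
    variable: str
    test: str
    group1: str
    group2: str
    summary1: str
    summary2: str
    n1: int
    n2: int
    statistic: Optional[float]
    p_value: Optional[float]
    label: Optional[str] = None


@dataclass
class CorrelationRow:
    x_variable: str
    y_variable: str
    method: str
    r: Optional[float]
    p_value: Optional[float]
    n_used: int
    group: str = "total"


@lru_cache(maxsize=1)
def _layout() -> dict:
    text = importlib.resources.files("simscore").joinpath("table_layout.yaml").read_text()
    return yaml.safe_load(text)


def table1_layout() -> List[dict]:
    return list(_layout()["table1"])


def correlation_layout() -> List[dict]:
    return list(_layout()["correlations"])


# ---------------------------------------------------------------------------
# elementary tests


def t_test(x: Sequence[float], y: Sequence[float], welch: bool = False):
    """Two-sided independent-samples t test (pooled variance by default).

    Degenerate case — both samples constant with equal means — returns
    statistic 0, p 1 instead of NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("t test needs at least two observations per group")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]):
    """Two-sided Mann-Whitney U. Exact null when min(n,m) <= 8 and the data
    are tie-free; otherwise normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("Mann-Whitney needs non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= EXACT_MW_MAX and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square(table: np.ndarray, continuity: bool = False):
    """Pearson chi-square on a contingency table (no Yates correction on
    2x2 unless requested)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise DomainError("contingency counts must be non-negative")
    res = sps.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2xk(table: np.ndarray, max_tables: int = 5_000_000):
    """Fisher-Freeman-Halton exact test for a 2×k table.

    Two-sided p-value: the sum of the conditional (multivariate
    hypergeometric) probabilities of every table with the observed margins
    whose probability does not exceed the observed table's. Reduces to the
    classic two-sided Fisher test for 2×2. Enumeration runs over the k−1
    smallest column totals, so it is fast whenever at most one column is
    large.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise DomainError("fisher_exact_2xk needs a 2xk table")
    if (table < 0).any():
        raise DomainError("contingency counts must be non-negative")
    col_totals = table.sum(axis=0)
    keep = col_totals > 0
    table = table[:, keep]
    col_totals = col_totals[keep]
    if table.shape[1] < 2:
        return math.nan, 1.0
    r1 = int(table[0].sum())
    n = int(table.sum())

    # sort columns ascending so the largest is the dependent one
    order = np.argsort(col_totals)
    cols = col_totals[order].tolist()
    obs = table[0, order].tolist()
    free_cols = cols[:-1]
    if int(np.prod([min(c, r1) + 1 for c in free_cols])) > max_tables:
        raise DomainError("table too large for exact enumeration")

    def log_prob(a: List[int]) -> float:
        # P(table | margins) = prod_j C(c_j, a_j) / C(n, r1)
        lp = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        for c, aj in zip(cols, a):
            lp += gammaln(c + 1) - gammaln(aj + 1) - gammaln(c - aj + 1)
        return lp

    lp_obs = log_prob(obs)
    p = 0.0
    ranges = [range(min(c, r1) + 1) for c in free_cols]
    last_col = cols[-1]
    for combo in itertools.product(*ranges):
        a_last = r1 - sum(combo)
        if a_last < 0 or a_last > last_col:
            continue
        lp = log_prob(list(combo) + [a_last])
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return math.nan, min(p, 1.0)


# ---------------------------------------------------------------------------
# cohort-level operations


def _two_groups(cohort: pd.DataFrame, group_col: str) -> List[str]:
    labels = [g for g in cohort[group_col].dropna().unique()]
    if len(labels) != 2:
        raise DomainError(
            f"exactly two groups required in {group_col!r}, found {labels!r}"
        )
    # stable, meaningful order: young before older when applicable
    if set(labels) == {"young", "older"}:
        return ["young", "older"]
    return sorted(map(str, labels))


def _fmt_mean_sd(v: pd.Series) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def _fmt_median_iqr(v: pd.Series) -> str:
    q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def compare_groups(
    cohort: pd.DataFrame,
    group_col: str,
    variable: str,
    test: str,
    scale: Optional[str] = None,
    level: Optional[str] = None,
    welch: bool = False,
) -> ComparisonRow:
    """Compare one variable between the two groups of ``group_col``.

    Continuous tests use listwise deletion on the variable; categorical
    tests build the 2×k contingency table of group × level. ``level`` names
    the positive level for proportion summaries (e.g. 'obese').
    """
    if test not in TESTS:
        raise DomainError(f"unknown test {test!r}")
    g1, g2 = _two_groups(cohort, group_col)
    sub = cohort[[group_col, variable]].dropna()
    a = sub.loc[sub[group_col] == g1, variable]
    b = sub.loc[sub[group_col] == g2, variable]
    if len(a) == 0 or len(b) == 0:
        raise DomainError(f"empty group for variable {variable!r}")

    if test in ("t_test", "mann_whitney"):
        a = a.astype(float)
        b = b.astype(float)
        if test == "t_test":
            stat, p = t_test(a, b, welch=welch)
            s1, s2 = _fmt_mean_sd(a), _fmt_mean_sd(b)
        else:
            stat, p = mann_whitney(a, b)
            s1, s2 = _fmt_median_iqr(a), _fmt_median_iqr(b)
        if scale == "mean_sd":
            s1, s2 = _fmt_mean_sd(a), _fmt_mean_sd(b)
        elif scale == "median_iqr":
            s1, s2 = _fmt_median_iqr(a), _fmt_median_iqr(b)
    else:
        ct = pd.crosstab(sub[group_col], sub[variable])
        ct = ct.reindex([g1, g2])
        counts = ct.to_numpy()
        if test == "chi_square":
            if level is not None and level in ct.columns:
                pos = ct[level].to_numpy()
                counts = np.column_stack([pos, counts.sum(axis=1) - pos])
            stat, p = chi_square(counts)
        else:
            stat, p = fisher_exact_2xk(counts)
        if level is not None and level in ct.columns:
            tot = ct.sum(axis=1)
            s1 = f"{ct.loc[g1, level]} ({100 * ct.loc[g1, level] / tot[g1]:.1f}%)"
            s2 = f"{ct.loc[g2, level]} ({100 * ct.loc[g2, level] / tot[g2]:.1f}%)"
        else:
            s1 = "; ".join(f"{c}: {ct.loc[g1, c]}" for c in ct.columns)
            s2 = "; ".join(f"{c}: {ct.loc[g2, c]}" for c in ct.columns)

    return ComparisonRow(
        variable=variable, test=test, group1=g1, group2=g2,
        summary1=s1, summary2=s2, n1=int(len(a)), n2=int(len(b)),
        statistic=None if (stat is not None and math.isnan(stat)) else stat,
        p_value=p,
    )


def correlate(
    cohort: pd.DataFrame,
    y_variable: str,
    method: str = "pearson",
    x_variable: str = "sims",
    group: str = "total",
) -> CorrelationRow:
    """Correlation of ``x_variable`` (siMS by default) with a biomarker.

    Listwise deletion; zero variance in either variable yields an undefined
    correlation (r and p None), not a number.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    sub = cohort[[x_variable, y_variable]].dropna().astype(float)
    n = len(sub)
    if n < 3:
        raise DomainError(f"need at least 3 complete pairs, have {n}")
    x = sub[x_variable].to_numpy()
    y = sub[y_variable].to_numpy()
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationRow(x_variable, y_variable, method, None, None, n, group)
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return CorrelationRow(
        x_variable, y_variable, method,
        float(res.statistic), float(res.pvalue), n, group,
    )


def build_table1(
    cohort: pd.DataFrame,
    group_col: str = "age_group",
    welch: bool = False,
) -> List[ComparisonRow]:
    """One comparison row per configured variable (baseline table surface).

    Variables absent from the cohort are skipped with a logged warning.
    """
    _two_groups(cohort, group_col)  # raises early on a one-group cohort
    rows = []
    for entry in table1_layout():
        variable = entry["variable"]
        if variable not in cohort.columns:
            logger.warning("table1: variable %r not in cohort, skipped", variable)
            continue
        row = compare_groups(
            cohort, group_col, variable,
            test=entry["test"], scale=entry.get("scale"),
            level=entry.get("level"), welch=welch,
        )
        row.label = entry.get("label", variable)
        rows.append(row)
    return rows


def build_correlations(
    cohort: pd.DataFrame,
    group_col: str = "age_group",
    x_variable: str = "sims",
) -> List[CorrelationRow]:
    """siMS correlation screen, overall and within each group."""
    groups = [("total", cohort)]
    if group_col in cohort.columns:
        groups += [(str(g), sub) for g, sub in cohort.groupby(group_col, observed=True)]
    rows = []
    for entry in correlation_layout():
        variable = entry["variable"]
        if variable not in cohort.columns or variable == x_variable:
            continue
        for name, sub in groups:
            try:
                rows.append(correlate(sub, variable, entry["method"], x_variable, name))
            except DomainError:
                logger.warning("correlation %s/%s skipped in group %s", x_variable,
                               variable, name)
    return rows


def sims_by_glyco(cohort: pd.DataFrame, group_col: str = "age_group") -> pd.DataFrame:
    """siMS mean ± SD per glycoregulation category, total and per group.

    Empty cells are absent rows; single-member cells report SD as NaN.
    """
    if "sims" not in cohort.columns or "glyco_label" not in cohort.columns:
        raise DomainError("cohort must be scored and glyco-labelled")
    frames = [("total", cohort)]
    if group_col in cohort.columns:
        frames += [(str(g), sub) for g, sub in cohort.groupby(group_col, observed=True)]
    records = []
    for group_name, sub in frames:
        for label, display in GLYCO_DISPLAY:
            v = sub.loc[sub["glyco_label"] == label, "sims"].dropna()
            if len(v) == 0:
                continue
            records.append({
                "group": group_name,
                "glyco_label": label,
                "display": display,
                "n": int(len(v)),
                "sims_mean": float(v.mean()),
                "sims_sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            })
    return pd.DataFrame.from_records(records)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional annotation; never used for filtering)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
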