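"""Baseline-characteristics tables, group comparisons and incidence rates.

Percentages use non-missing denominators (a participant missing a
categorical covariate is excluded from that row's denominator only).
Continuous covariates are compared with Welch's t-test, categorical with
chi-square, and biomarker distributions with a two-sided Mann-Whitney
test. Incidence rates carry exact Poisson 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import BIOMARKERS, DISEASES

CONTINUOUS_VARS = ["age", "n_chronic_diseases", "mmse"]
BINARY_VARS = DISEASES + ["memory_complaints", "apoe_e4"]
CATEGORICAL_VARS = ["sex", "education"]


@dataclass(frozen=True)
class IncidenceResult:
    """Events, person-years and the rate per 100 person-years with 95% CI."""

    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float


def incidence_rate(events: int, person_years: float, alpha: float = 0.05) -> IncidenceResult:
    """Incidence rate per 100 person-years with an exact Poisson CI.

    The CI inverts the chi-square representation of the Poisson
    distribution of the event count: lower = chi2.ppf(a/2, 2k)/2,
    upper = chi2.ppf(1-a/2, 2k+2)/2, scaled by person-years. Zero events
    give a lower bound of exactly 0.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    rate = 100.0 * events / person_years
    lo = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return IncidenceResult(
        events=int(events),
        person_years=float(person_years),
        rate=rate,
        ci_low=100.0 * lo / person_years,
        ci_high=100.0 * hi / person_years,
    )


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (n <= 20 in both arms),
    tie-corrected normal approximation otherwise.

    Returns ``(U, p)`` with U the statistic for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    small = len(x) <= 20 and len(y) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _pct(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else float("nan")


def summarize_by_group(
    table: pd.DataFrame,
    group_col: str = "incident_dementia",
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    categorical: list[str] | None = None,
    biomarkers: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy baseline-characteristics table by group (one row per variable/level).

    Columns: variable, level, per-group summaries (``mean_sd`` or
    ``n``/``pct``), overall summary and a two-sided p-value. Percentages
    are computed on non-missing denominators.
    """
    if group_col not in table.columns:
        raise ValueError(f"group column {group_col!r} not found")
    groups = [g for g in table[group_col].dropna().unique()]
    groups.sort(key=str)
    if any(len(table[table[group_col] == g]) == 0 for g in groups) or not groups:
        raise ValueError("each group must be non-empty")
    continuous = CONTINUOUS_VARS if continuous is None else continuous
    binary = BINARY_VARS if binary is None else binary
    categorical = CATEGORICAL_VARS if categorical is None else categorical
    biomarkers = BIOMARKERS if biomarkers is None else biomarkers

    rows: list[dict] = []

    def subset(g):
        return table[table[group_col] == g]

    for var in continuous:
        if var not in table.columns:
            continue
        arms = [subset(g)[var].dropna() for g in groups]
        p = np.nan
        if len(arms) == 2 and all(len(a) > 1 for a in arms):
            p = stats.ttest_ind(arms[0], arms[1], equal_var=False).pvalue
        row = {"variable": var, "level": "", "type": "continuous", "p": p,
               "total": _fmt_mean_sd(table[var].dropna())}
        for g, a in zip(groups, arms):
            row[f"{g}"] = _fmt_mean_sd(a)
        rows.append(row)

    for var in binary:
        if var not in table.columns:
            continue
        nonmiss = table[var].notna()
        counts = [int((subset(g)[var] == 1).sum()) for g in groups]
        denoms = [int(subset(g)[var].notna().sum()) for g in groups]
        p = np.nan
        ctab = pd.crosstab(table.loc[nonmiss, group_col], table.loc[nonmiss, var])
        if ctab.shape == (len(groups), 2) and (ctab.values > 0).all():
            p = stats.chi2_contingency(ctab, correction=False)[1]
        row = {"variable": var, "level": "yes", "type": "binary", "p": p,
               "total": _pct(int((table[var] == 1).sum()), int(nonmiss.sum())),
               "total_n": int((table[var] == 1).sum())}
        for g, c, d in zip(groups, counts, denoms):
            row[f"{g}"] = _pct(c, d)
            row[f"{g}_n"] = c
        rows.append(row)

    for var in categorical:
        if var not in table.columns:
            continue
        nonmiss = table[var].notna()
        levels = sorted(table.loc[nonmiss, var].unique(), key=str)
        ctab = pd.crosstab(table.loc[nonmiss, group_col], table.loc[nonmiss, var])
        p = stats.chi2_contingency(ctab, correction=False)[1] if ctab.size and (ctab.values.sum(axis=1) > 0).all() else np.nan
        for level in levels:
            row = {"variable": var, "level": str(level), "type": "categorical", "p": p,
                   "total": _pct(int(((table[var] == level) & nonmiss).sum()), int(nonmiss.sum())),
                   "total_n": int(((table[var] == level) & nonmiss).sum())}
            for g in groups:
                sub = subset(g)
                row[f"{g}"] = _pct(int((sub[var] == level).sum()), int(sub[var].notna().sum()))
                row[f"{g}_n"] = int((sub[var] == level).sum())
            rows.append(row)

    for var in biomarkers:
        if var not in table.columns:
            continue
        arms = [subset(g)[var].dropna().to_numpy() for g in groups]
        p = np.nan
        if len(arms) == 2 and all(len(a) > 0 for a in arms):
            _, p = mann_whitney(arms[0], arms[1])
        row = {"variable": var, "level": "", "type": "biomarker", "p": p,
               "total": f"{table[var].median():.3f}"}
        for g, a in zip(groups, arms):
            row[f"{g}"] = f"{np.median(a):.3f}" if len(a) else ""
        rows.append(row)

    return pd.DataFrame(rows)


def cohort_incidence(
    table: pd.DataFrame, outcome: str = "all_cause"
) -> IncidenceResult:
    """All-cause or AD incidence rate of a cohort table.

    Person-years are the sum of follow-up for everyone at risk (the same
    denominator for both outcomes; the cause-specific AD rate restricts
    the numerator to AD events only).
    """
    if outcome == "all_cause":
        events = table["event"].isin(["ad_dementia", "other_dementia"]).sum()
    elif outcome == "ad":
        events = (table["event"] == "ad_dementia").sum()
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return incidence_rate(int(events), float(table["followup_years"].sum()))
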