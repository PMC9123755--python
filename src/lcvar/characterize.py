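"""Between-cluster characterisation of trait data.

One-way ANOVAs with generalised eta-squared for each continuous trait,
Tukey HSD post-hoc contrasts, Pearson chi-squared for balanced categorical
margins, and an exact Fisher test (full r x c enumeration, probability-
ordering two-sided rule) for sparse ones such as gender x cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary with generalised eta-squared.

    For a one-way between-subject design the generalised eta-squared reduces
    to SS_num / (SS_num + SS_den).
    """

    ss_num: float
    ss_den: float
    df_num: int
    df_den: int
    f: float
    p: float
    eta2_g: float


def anova_from_sums(
    ss_num: float, ss_den: float, df_num: int, df_den: int,
) -> AnovaResult:
    """Recover F, p and eta2_g from printed sums of squares and df."""
    if ss_num < 0 or ss_den < 0:
        raise ValueError("sums of squares must be non-negative")
    f = (ss_num / df_num) / (ss_den / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    eta2 = ss_num / (ss_num + ss_den) if (ss_num + ss_den) > 0 else 0.0
    return AnovaResult(ss_num, ss_den, df_num, df_den, float(f), p, float(eta2))


def _group_arrays(values, groups) -> tuple[list[np.ndarray], list]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    levels = list(pd.unique(groups))
    arrays = [values[groups == g] for g in levels]
    for g, arr in zip(levels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    return arrays, levels


def oneway_anova(values, groups) -> AnovaResult:
    """Between-group one-way ANOVA on raw values (listwise NaN removal)."""
    arrays, _ = _group_arrays(values, groups)
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_num = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_den = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_num = len(arrays) - 1
    df_den = len(all_vals) - len(arrays)
    if ss_den == 0:
        return AnovaResult(float(ss_num), 0.0, df_num, df_den,
                           0.0 if ss_num == 0 else np.inf,
                           1.0 if ss_num == 0 else 0.0,
                           0.0 if ss_num == 0 else 1.0)
    return anova_from_sums(float(ss_num), float(ss_den), df_num, df_den)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TukeyContrast:
    group_a: object
    group_b: object
    delta: float          # mean(b) - mean(a)
    p: float
    ci_low: float
    ci_high: float


def tukey_hsd(values, groups, alpha: float = 0.05) -> list[TukeyContrast]:
    """All pairwise mean contrasts under the studentized-range distribution.

    ``delta`` follows the (b - a) convention: the later-listed group's mean
    minus the earlier one's.
    """
    arrays, levels = _group_arrays(values, groups)
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    out = []
    for i, j in [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]:
        out.append(
            TukeyContrast(
                group_a=levels[i],
                group_b=levels[j],
                delta=float(res.statistic[j, i]),
                p=float(res.pvalue[j, i]),
                ci_low=float(ci.low[j, i]),
                ci_high=float(ci.high[j, i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact Fisher test for r x c tables
# ---------------------------------------------------------------------------

def _enumerate_tables(row_margins, col_margins):
    """Yield log-probabilities of every table with the given margins.

    The multivariate hypergeometric log-probability of a table {n_ij} is
    sum lg(r_i!) + sum lg(c_j!) - lg(N!) - sum lg(n_ij!), accumulated via
    log-factorials for numerical stability.
    """
    rows = list(row_margins)
    cols = list(col_margins)
    n = sum(rows)
    base = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols) \
        - lgamma(n + 1)

    def rec(i, remaining_cols, acc):
        if i == len(rows) - 1:
            yield acc - sum(lgamma(c + 1) for c in remaining_cols)
            return
        yield from _fill_row(rows[i], remaining_cols, 0, acc, i, [])

    def _fill_row(left, rem, j, acc, i, filled):
        if j == len(cols) - 1:
            if left > rem[j]:
                return
            new_rem = [r - f for r, f in zip(rem, filled + [left])]
            yield from rec(i + 1, new_rem, acc - lgamma(left + 1))
            return
        hi = min(left, rem[j])
        for v in range(hi + 1):
            yield from _fill_row(
                left - v, rem, j + 1, acc - lgamma(v + 1), i, filled + [v]
            )

    yield from rec(0, cols, base)


def _table_logprob(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
        - sum(lgamma(v + 1) for v in table.ravel())
    )


def fisher_exact_rxc(table) -> float:
    """Two-sided exact Fisher p for an r x c count table.

    Enumerates every table sharing the observed margins and sums the
    probabilities of all tables no more probable than the observed one
    (probability-ordering rule, the convention of the usual statistical
    software).  Intended for modest totals; refuses tables above 10,000
    observations.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(table.sum())
    if total > 10_000:
        raise ValueError("table total exceeds the enumeration bound of 10,000")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        warnings.warn(
            "degenerate margin (zero row or column total); p = 1", stacklevel=2
        )
        return 1.0
    obs = _table_logprob(table)
    cutoff = obs + 1e-7          # tolerance for ties in floating point
    p = 0.0
    for lp in _enumerate_tables(rows.tolist(), cols.tolist()):
        if lp <= cutoff:
            p += np.exp(lp)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Pearson chi-squared
# ---------------------------------------------------------------------------

def pearson_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq == 0).any():
        raise ValueError("zero expected cell count")
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

def characterize_clusters(
    traits: pd.DataFrame,
    labels: dict,
    trait_columns: Sequence[str] | None = None,
    gender_column: str | None = "gender",
    correction: str | None = None,
) -> dict:
    """Run the full between-cluster battery on a trait table.

    ``traits`` needs a ``participant_id`` column; cluster labels come from
    the fit's hard assignment.  Participants with a missing value on a trait
    are dropped listwise per test.  Returns a dict with the ANOVA table, the
    Tukey contrasts for each trait, and (when a gender column exists) the
    Fisher exact p for the gender x cluster table.  ``correction='holm'``
    optionally adjusts the ANOVA p-values (off by default).
    """
    df = traits.copy()
    df["_cluster"] = df["participant_id"].map(labels)
    df = df[df["_cluster"].notna()]
    if trait_columns is None:
        trait_columns = [
            c for c in df.columns
            if c not in ("participant_id", "cluster", "_cluster", gender_column)
            and pd.api.types.is_numeric_dtype(df[c])
        ]

    anova_rows, contrasts = [], {}
    for col in trait_columns:
        sub = df[df[col].notna()]
        res = oneway_anova(sub[col], sub["_cluster"])
        anova_rows.append(
            {"outcome": col, "ss_num": res.ss_num, "ss_den": res.ss_den,
             "df_num": res.df_num, "df_den": res.df_den,
             "F": res.f, "p": res.p, "eta2_g": res.eta2_g}
        )
        contrasts[col] = tukey_hsd(sub[col], sub["_cluster"])
    anova_table = pd.DataFrame(anova_rows)
    if correction == "holm" and len(anova_table):
        from statsmodels.stats.multitest import multipletests

        anova_table["p_adj"] = multipletests(anova_table["p"], method="holm")[1]

    out = {"anova": anova_table, "tukey": contrasts}
    if gender_column and gender_column in df.columns:
        tab = pd.crosstab(df["_cluster"], df[gender_column])
        out["gender_table"] = tab
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["gender_fisher_p"] = fisher_exact_rxc(tab.to_numpy())
    return out
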