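"""Descriptive and bivariate cohort statistics.

Implements the two-group comparison battery used for the study-population
tables: Shapiro-Wilk normality testing per group, a normality-gated choice
between Welch's t-test and the two-sided Mann-Whitney U test (asymptotic,
with tie-corrected variance and continuity correction), tiered Spearman
rank-correlation matrices computed independently per group, and
reconstruction of ordinal category counts from printed percentage rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .simulate import CohortTable

NORMALITY_ALPHA = 0.05
SIGNIFICANCE_TIERS = (0.001, 0.01, 0.05)


@dataclass
class GroupComparison:
    """Result of one variable's two-group comparison."""

    variable: str
    test: str | None  # "welch" | "mann-whitney" | None (no test run)
    statistic: float | None
    p_value: float | None
    normality_p: tuple[float, float] | None = None
    summary_group1: dict = field(default_factory=dict)
    summary_group2: dict = field(default_factory=dict)
    kind: str = "continuous"


@dataclass
class CorrelationMatrix:
    """All-pairs Spearman correlations for one group."""

    group: int
    variables: tuple
    rho: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame  # "none" | "0.05" | "0.01" | "0.001" | "" (diagonal/NA)


def reconstruct_counts(percentages, n: int) -> list[int]:
    """Invert a printed percentage row back to per-category counts.

    Counts are ``round(p * n / 100)`` with half-up rounding.  A consistency
    warning is raised when the counts do not sum to ``n`` or when
    re-percentaging (half-up to integer percent) does not reproduce the
    input row.
    """
    percentages = list(percentages)
    if any(not 0 <= p <= 100 for p in percentages):
        raise InputError("percentages must lie in [0, 100]")
    if n <= 0:
        raise InputError("n must be positive")
    counts = [int(np.floor(p * n / 100.0 + 0.5)) for p in percentages]
    if sum(counts) != n:
        warnings.warn(
            f"reconstructed counts sum to {sum(counts)}, not n={n}",
            UserWarning,
            stacklevel=2,
        )
    back = [int(np.floor(c * 100.0 / n + 0.5)) for c in counts]
    if back != [int(np.floor(p + 0.5)) for p in percentages]:
        warnings.warn(
            f"re-percentaging {counts} gives {back}, not the input row",
            UserWarning,
            stacklevel=2,
        )
    return counts


def _expand_counts(counts) -> np.ndarray:
    return np.repeat(np.arange(len(counts), dtype=float), counts)


def _mw_asymptotic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: midranks, tie-corrected variance,
    continuity correction.  Degenerate (zero-variance) data give p = 1."""
    tie_sd = np.concatenate([a, b]).std()
    if tie_sd == 0:
        warnings.warn(
            "all observations fall in one tied category; p set to 1",
            UserWarning,
            stacklevel=3,
        )
        return len(a) * len(b) / 2.0, 1.0
    res = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_ordinal(counts_a, counts_b) -> GroupComparison:
    """Tie- and continuity-corrected Mann-Whitney U on two count vectors
    over a shared category ladder."""
    counts_a, counts_b = list(counts_a), list(counts_b)
    if len(counts_a) != len(counts_b):
        raise InputError("count vectors must share the category ladder")
    n_a, n_b = sum(counts_a), sum(counts_b)
    if n_a < 1 or n_b < 1:
        raise InputError("each group must contain at least one observation")
    a, b = _expand_counts(counts_a), _expand_counts(counts_b)
    u, p = _mw_asymptotic(a, b)
    pct = lambda counts, n: {  # noqa: E731
        f"cat{k}": 100.0 * c / n for k, c in enumerate(counts)
    }
    return GroupComparison(
        variable="",
        test="mann-whitney",
        statistic=u,
        p_value=p,
        summary_group1=pct(counts_a, n_a),
        summary_group2=pct(counts_b, n_b),
        kind="ordinal",
    )


def welch_t(values_a, values_b) -> GroupComparison:
    """Welch's unequal-variance t-test, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("Welch's test needs at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise InputError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        variable="",
        test="welch",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_group1=_continuous_summary(a),
        summary_group2=_continuous_summary(b),
    )


def normality_test(values) -> float:
    """Shapiro-Wilk p-value."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise InputError("normality test needs n >= 3")
    if np.ptp(v) == 0:
        raise InputError("normality test undefined for a constant vector")
    return float(sps.shapiro(v).pvalue)


def _continuous_summary(v: np.ndarray) -> dict:
    q1, q3 = np.percentile(v, [25, 75])  # linear-interpolation quantiles
    return {
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "sd": float(np.std(v, ddof=1)),
        "iqr": float(q3 - q1),
    }


def compare_groups(cohort: CohortTable) -> list[GroupComparison]:
    """Normality-gated two-group comparison of every cohort column.

    Continuous variables: Shapiro-Wilk per group at 0.05; Welch's t when
    normality is not rejected in *both* groups, Mann-Whitney otherwise.
    Ordinal/binary variables are ranks by construction and always use
    Mann-Whitney.  Group-restricted variables are summarized for their group
    only, without a test.
    """
    g1 = cohort.group_mask(1)
    g2 = cohort.group_mask(0)
    if g1.sum() < 2 or g2.sum() < 2:
        raise InputError("compare_groups needs >= 2 participants per group")
    results = []
    for name in list(cohort.covariate_names) + list(cohort.dependent):
        col = cohort.data[name]
        if name in cohort.restricted:
            vals = col[g1].dropna().to_numpy(dtype=float)
            results.append(
                GroupComparison(
                    variable=name,
                    test=None,
                    statistic=None,
                    p_value=None,
                    summary_group1=_continuous_summary(vals) if len(vals) else {},
                    kind="restricted",
                )
            )
            continue
        a = col[g1].to_numpy(dtype=float)
        b = col[g2].to_numpy(dtype=float)
        if name in cohort.ordinal:
            cats = np.unique(np.concatenate([a, b]))
            counts_a = [int(np.sum(a == c)) for c in cats]
            counts_b = [int(np.sum(b == c)) for c in cats]
            cmp = mann_whitney_ordinal(counts_a, counts_b)
            cmp.variable = name
            results.append(cmp)
            continue
        np1 = normality_test(a)
        np2 = normality_test(b)
        if np1 > NORMALITY_ALPHA and np2 > NORMALITY_ALPHA:
            cmp = welch_t(a, b)
        else:
            u, p = _mw_asymptotic(a, b)
            cmp = GroupComparison(
                variable=name,
                test="mann-whitney",
                statistic=u,
                p_value=p,
                summary_group1=_continuous_summary(a),
                summary_group2=_continuous_summary(b),
            )
        cmp.variable = name
        cmp.normality_p = (np1, np2)
        results.append(cmp)
    return results


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for threshold in SIGNIFICANCE_TIERS:
        if p < threshold:
            return str(threshold)
    return "none"


def spearman_matrix(cohort: CohortTable, group: int) -> CorrelationMatrix:
    """All-pairs Spearman rho with significance tiers, within one group.

    Group-restricted columns are included only for the group they are
    measured in.  Constant columns yield undefined (NaN) correlations for
    their pairs, marked with an empty tier.
    """
    mask = cohort.group_mask(group)
    if mask.sum() < 4:
        raise InputError("spearman_matrix needs >= 4 participants in the group")
    names = [
        c
        for c in list(cohort.covariate_names) + list(cohort.dependent)
        if c not in cohort.restricted or group == 1
    ]
    sub = cohort.data.loc[mask, names].astype(float)
    k = len(names)
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        rho_arr, p_arr = sps.spearmanr(sub.to_numpy())
    if k == 2:  # scipy returns scalars for two columns
        rho_arr = np.array([[1.0, rho_arr], [rho_arr, 1.0]])
        p_arr = np.array([[np.nan, p_arr], [p_arr, np.nan]])
    rho = pd.DataFrame(rho_arr, index=names, columns=names)
    p = pd.DataFrame(p_arr, index=names, columns=names)
    np.fill_diagonal(rho.values, 1.0)
    np.fill_diagonal(p.values, np.nan)
    tier = p.map(_tier)
    np.fill_diagonal(tier.values, "")
    return CorrelationMatrix(group=group, variables=tuple(names), rho=rho, p=p, tier=tier)


# ---------------------------------------------------------------------------
# report shaping


def ordinal_report(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Ordinal-variable report: per-category percentages per group plus p."""
    rows = []
    for c in comparisons:
        if c.kind != "ordinal":
            continue
        row = {"variable": c.variable}
        for grp, summary in (("group1", c.summary_group1), ("group2", c.summary_group2)):
            for cat, pct in summary.items():
                row[f"{grp}_{cat}_pct"] = pct
        row["p_value"] = c.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def continuous_report(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Continuous-variable report: mean/median/SD/IQR, normality p, test, p."""
    rows = []
    for c in comparisons:
        if c.kind not in ("continuous", "restricted"):
            continue
        row = {"variable": c.variable}
        for grp, summary in (("group1", c.summary_group1), ("group2", c.summary_group2)):
            for stat in ("mean", "median", "sd", "iqr"):
                row[f"{grp}_{stat}"] = summary.get(stat)
        if c.normality_p is not None:
            row["normality_p_group1"], row["normality_p_group2"] = c.normality_p
        row["test"] = c.test
        row["p_value"] = c.p_value
        rows.append(row)
    return pd.DataFrame(rows)
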