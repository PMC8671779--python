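"""Between-group comparison machinery for biotype characterisation.

Chi-squared and t-tests for demographics, one-way ANOVA with
Bonferroni-corrected pairwise contrasts for three-group comparisons
(two patient clusters vs controls), Benjamini-Hochberg FDR applied
independently within each comparison family (e.g. "EEG graph theory
parameters"), and Mann-Whitney U with a tie-corrected normal
approximation for the small first-episode subgroup contrasts, which are
deliberately left uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    """One statistical comparison, before and after FDR adjustment."""

    name: str
    statistic: float
    p_raw: float
    df: float | None = None
    p_adjusted: float | None = None
    family: str | None = None
    groups: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def chi_square(counts, name: str = "chi_square",
               family: str | None = None) -> ComparisonResult:
    """Pearson chi-squared test of independence on a contingency table
    (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-d contingency table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be > 0")
    return ComparisonResult(
        name=name,
        statistic=float(res.statistic),
        df=float(res.dof),
        p_raw=float(res.pvalue),
        family=family,
    )


def anova_bonferroni(
    values,
    groups,
    name: str = "anova",
    family: str | None = None,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA plus pairwise t contrasts with Bonferroni correction.

    Pairwise p-values are multiplied by the number of pairs and capped at
    1.  Every group needs >= 2 members.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    samples = {g: values[groups == g] for g in labels}
    for g, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"group {g!r} has < 2 members")
    f_stat, p = sps.f_oneway(*samples.values())
    n, k = len(values), len(labels)
    overall = ComparisonResult(
        name=name,
        statistic=float(f_stat),
        df=float(k - 1),
        p_raw=float(p),
        family=family,
        groups=tuple(str(g) for g in labels),
        extra={"df_resid": float(n - k)},
    )
    pairs = [
        (labels[i], labels[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    contrasts = []
    for a, b in pairs:
        t_stat, p_pair = sps.ttest_ind(samples[a], samples[b])
        contrasts.append(
            ComparisonResult(
                name=f"{name}:{a}-vs-{b}",
                statistic=float(t_stat),
                df=float(len(samples[a]) + len(samples[b]) - 2),
                p_raw=float(p_pair),
                p_adjusted=float(min(p_pair * len(pairs), 1.0)),
                family=family,
                groups=(str(a), str(b)),
            )
        )
    return overall, contrasts


def bh_fdr(
    p_values, families=None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, applied within each family
    independently when ``families`` tags are given."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.empty_like(p)
    if families is None:
        families = np.zeros(len(p))
    families = np.asarray(families)
    for fam in pd.unique(families):
        idx = families == fam
        adjusted[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adjusted


def adjust_results(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Fill ``p_adjusted`` across a result list, family by family."""
    if not results:
        return results
    p = np.array([r.p_raw for r in results])
    fams = np.array([r.family or "default" for r in results])
    adj = bh_fdr(p, fams)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


def mann_whitney(
    x,
    y,
    alternative: str = "two-sided",
    name: str = "mann_whitney",
    family: str | None = None,
) -> ComparisonResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Reports U (of the first sample), the z statistic (continuity-
    corrected, as is standard for the normal approximation to a discrete
    rank statistic), and the normal-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:
        raise ValueError("all values tied across both samples")
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma_sq)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ComparisonResult(
        name=name,
        statistic=float(u1),
        p_raw=float(min(p, 1.0)),
        family=family,
        extra={"z": float(z), "U": float(u1)},
    )


def _markers(p_adj: float | None, thresholds=(0.05, 0.01),
             symbols=("*", "**")) -> str:
    if p_adj is None:
        return ""
    mark = ""
    for thr, sym in zip(sorted(thresholds, reverse=True),
                        symbols):
        if p_adj < thr:
            mark = sym
    return mark


def report_tables(
    results: list[ComparisonResult],
    feature_table: pd.DataFrame | None = None,
    group_labels=None,
    thresholds: tuple[float, float] = (0.05, 0.01),
    symbols: tuple[str, str] = ("*", "**"),
) -> pd.DataFrame:
    """Render comparison results as a mean (SD)-per-group table.

    One row per comparison (metric); one column per group with
    ``mean (SD)`` plus significance markers on the adjusted p at the given
    thresholds, followed by raw and adjusted p columns.  With no results,
    a header-only frame is returned.
    """
    groups = []
    if feature_table is not None and group_labels is not None:
        group_labels = np.asarray(group_labels)
        groups = [g for g in pd.unique(group_labels)]
    columns = [str(g) for g in groups] + ["statistic", "p_raw", "p_adjusted"]
    rows = {}
    for r in results:
        metric = r.name.split(":")[0]
        row = {}
        if feature_table is not None and metric in feature_table.columns:
            for g in groups:
                vals = feature_table.loc[group_labels == g, metric]
                mark = _markers(r.p_adjusted, thresholds, symbols)
                row[str(g)] = f"{vals.mean():.3f} ({vals.std(ddof=1):.3f}){mark}"
        row["statistic"] = round(r.statistic, 4)
        row["p_raw"] = round(r.p_raw, 6)
        row["p_adjusted"] = (
            round(r.p_adjusted, 6) if r.p_adjusted is not None else np.nan
        )
        rows[metric] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
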