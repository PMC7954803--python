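"""Cohort-level paired statistics over per-patient metric tables.

The comparison procedure mirrors common practice in small reader-study
cohorts: a Shapiro–Wilk normality gate decides between a parametric and a
nonparametric branch, at significance level 0.05 throughout.

* two paired conditions — paired t test when the paired differences pass
  the gate, otherwise the two-sided Wilcoxon matched-pairs signed-rank
  test with an exact small-sample p value (n <= 25);
* three or more conditions — repeated-measures one-way ANOVA with the
  Geisser–Greenhouse sphericity correction plus Fisher's-LSD pairwise
  comparisons when every condition passes the gate, otherwise the Friedman
  test plus uncorrected Dunn's pairwise comparisons.  No multiplicity
  correction is applied in either branch.

Missing values (e.g. undefined specificity in whole-gland-positive
patients) are handled by complete-case deletion restricted to the
conditions involved in each comparison, and the n actually used is always
reported.  Summaries are median + IQR (linear-interpolation percentiles)
plus range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

#: largest sample for which the exact signed-rank null distribution is used
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class Summary:
    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float
    mean: float
    sd: float
    percentile_method: str = "linear"


@dataclass(frozen=True)
class NormalityVerdict:
    normal: bool
    p_value: float | None
    degenerate: bool = False
    note: str = ""


@dataclass
class PosthocComparison:
    condition_a: str
    condition_b: str
    statistic: float
    p_value: float
    test: str


@dataclass
class ComparisonReport:
    conditions: list[str]
    n: int
    normality: dict[str, NormalityVerdict]
    test: str
    statistic: float | None
    p_value: float | None
    alpha: float = ALPHA
    degenerate: bool = False
    n_zero_differences: int = 0
    posthoc: list[PosthocComparison] = field(default_factory=list)
    summaries: dict[str, Summary] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha


def summarize(values) -> Summary | None:
    """Median + IQR + range; missing values are dropped first."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        return None
    return Summary(
        n=int(v.size),
        median=float(np.median(v)),
        q25=float(np.percentile(v, 25)),
        q75=float(np.percentile(v, 75)),
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
    )


def normality_gate(values, alpha: float = ALPHA) -> NormalityVerdict:
    """Shapiro–Wilk gate: normal iff p > alpha.

    Constant input is degenerate: the verdict is non-normal with a note.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 3:
        raise ValueError(f"normality gate requires n >= 3, got {v.size}")
    if np.ptp(v) == 0.0:
        warnings.warn("constant sample: Shapiro-Wilk undefined, treating as non-normal")
        return NormalityVerdict(
            normal=False, p_value=None, degenerate=True, note="constant sample"
        )
    stat = stats.shapiro(v)
    return NormalityVerdict(normal=bool(stat.pvalue > alpha), p_value=float(stat.pvalue))


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank


def wilcoxon_exact(differences) -> tuple[float, float]:
    """Two-sided exact Wilcoxon signed-rank test.

    Zero differences are dropped (classic convention), |d| are midranked,
    and the exact permutation distribution of the positive-rank sum W+ over
    all 2^n sign assignments is built by dynamic programming (ties allowed:
    midranks are doubled to stay integral).  Returns (W+, two-sided p),
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2.0 * ranks).astype(np.int64)  # midranks doubled -> ints
    w2 = int(r2[d > 0].sum())
    total = int(r2.sum())
    # dp[s] = number of sign assignments with doubled positive-rank sum s
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in r2:
        dp[r:] = dp[r:] + dp[:-r] if r > 0 else dp[r:]
    dp /= 2.0**n
    p_low = float(dp[: w2 + 1].sum())
    p_high = float(dp[w2:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    return ranks[d > 0].sum(), p


def _wilcoxon(differences) -> tuple[float, float, int]:
    """Two-sided Wilcoxon matched-pairs test; exact for n <= 25.

    Returns (W+, p, number of zero differences dropped).
    """
    d = np.asarray(differences, dtype=float)
    n_zero = int((d == 0.0).sum())
    nz = d[d != 0.0]
    if nz.size == 0:
        return 0.0, 1.0, n_zero
    if nz.size <= WILCOXON_EXACT_MAX_N:
        w, p = wilcoxon_exact(nz)
        return w, p, n_zero
    res = stats.wilcoxon(
        nz, alternative="two-sided", correction=True, method="approx"
    )
    return float(res.statistic), float(res.pvalue), n_zero


# ---------------------------------------------------------------------------
# two-condition comparison


def compare_two(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alpha: float = ALPHA,
) -> ComparisonReport:
    """Paired two-condition comparison on complete cases.

    The normality gate is applied to the paired differences; a normal
    verdict selects the two-sided paired t test, otherwise the Wilcoxon
    matched-pairs signed-rank test.
    """
    sub = table[[condition_a, condition_b]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    a = sub[condition_a].to_numpy(dtype=float)
    b = sub[condition_b].to_numpy(dtype=float)
    d = a - b
    summaries = {condition_a: summarize(a), condition_b: summarize(b)}

    if np.all(d == 0.0):
        return ComparisonReport(
            conditions=[condition_a, condition_b],
            n=n,
            normality={"differences": NormalityVerdict(False, None, True, "all differences zero")},
            test="degenerate (identical conditions)",
            statistic=None,
            p_value=1.0,
            alpha=alpha,
            degenerate=True,
            n_zero_differences=n,
            summaries=summaries,
        )

    verdict = normality_gate(d, alpha=alpha)
    if verdict.normal:
        res = stats.ttest_rel(a, b)
        return ComparisonReport(
            conditions=[condition_a, condition_b],
            n=n,
            normality={"differences": verdict},
            test="paired t (two-sided)",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            alpha=alpha,
            summaries=summaries,
        )
    w, p, n_zero = _wilcoxon(d)
    method = "exact" if (d != 0).sum() <= WILCOXON_EXACT_MAX_N else "normal approximation"
    return ComparisonReport(
        conditions=[condition_a, condition_b],
        n=n,
        normality={"differences": verdict},
        test=f"Wilcoxon matched-pairs signed-rank (two-sided, {method})",
        statistic=float(w),
        p_value=float(p),
        alpha=alpha,
        n_zero_differences=n_zero,
        summaries=summaries,
    )


# ---------------------------------------------------------------------------
# >= 3 conditions


def _friedman_dunn(x: np.ndarray, conditions: list[str], alpha: float) -> tuple:
    """Friedman omnibus + uncorrected Dunn's pairwise z tests on mean ranks."""
    stat, p = stats.friedmanchisquare(*(x[:, j] for j in range(x.shape[1])))
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            posthoc.append(
                PosthocComparison(
                    condition_a=conditions[i],
                    condition_b=conditions[j],
                    statistic=float(z),
                    p_value=float(2.0 * stats.norm.sf(abs(z))),
                    test="Dunn (uncorrected)",
                )
            )
    return float(stat), float(p), posthoc


def _rm_anova_gg(x: np.ndarray, conditions: list[str], alpha: float) -> tuple:
    """Repeated-measures one-way ANOVA with Geisser–Greenhouse correction,
    plus Fisher's LSD pairwise t tests on the ANOVA residual error."""
    import pingouin as pg

    n, k = x.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(conditions, n),
            "value": x.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject", correction=True
    )
    row = aov.iloc[0]
    f_stat = float(row["F"])
    # column naming differs between pingouin releases
    gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), None)
    unc_col = next(c for c in ("p_unc", "p-unc") if c in aov.columns)
    if gg_col is not None and not pd.isna(row[gg_col]):
        p_gg = float(row[gg_col])
    else:
        p_gg = float(row[unc_col])

    # Fisher's LSD: t on condition-mean differences with the RM residual MS
    grand = x.mean()
    subj_mean = x.mean(axis=1, keepdims=True)
    cond_mean = x.mean(axis=0, keepdims=True)
    resid = x - subj_mean - cond_mean + grand
    df_res = (n - 1) * (k - 1)
    ms_res = float((resid**2).sum() / df_res)
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(cond_mean[0, i] - cond_mean[0, j])
            se = math.sqrt(2.0 * ms_res / n)
            t = diff / se if se > 0 else 0.0
            posthoc.append(
                PosthocComparison(
                    condition_a=conditions[i],
                    condition_b=conditions[j],
                    statistic=float(t),
                    p_value=float(2.0 * stats.t.sf(abs(t), df_res)) if se > 0 else 1.0,
                    test="Fisher LSD",
                )
            )
    return f_stat, p_gg, posthoc


def compare_many(
    table: pd.DataFrame,
    conditions: list[str],
    alpha: float = ALPHA,
) -> ComparisonReport:
    """Compare >= 3 paired conditions on complete cases.

    All conditions normal -> RM-ANOVA (Geisser–Greenhouse) + Fisher's LSD;
    otherwise Friedman + uncorrected Dunn's.
    """
    if len(conditions) < 3:
        raise ValueError("compare_many requires >= 3 conditions")
    sub = table[list(conditions)].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")
    x = sub.to_numpy(dtype=float)
    summaries = {c: summarize(x[:, j]) for j, c in enumerate(conditions)}

    if np.all(np.ptp(x, axis=1) == 0.0):
        return ComparisonReport(
            conditions=list(conditions),
            n=n,
            normality={},
            test="degenerate (identical conditions)",
            statistic=None,
            p_value=1.0,
            alpha=alpha,
            degenerate=True,
            summaries=summaries,
        )

    normality = {c: normality_gate(x[:, j], alpha=alpha) for j, c in enumerate(conditions)}
    all_normal = all(v.normal for v in normality.values())
    if all_normal:
        stat, p, posthoc = _rm_anova_gg(x, list(conditions), alpha)
        test = "repeated-measures one-way ANOVA (Geisser-Greenhouse) + Fisher LSD"
    else:
        stat, p, posthoc = _friedman_dunn(x, list(conditions), alpha)
        test = "Friedman + uncorrected Dunn"
    return ComparisonReport(
        conditions=list(conditions),
        n=n,
        normality=normality,
        test=test,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        posthoc=posthoc,
        summaries=summaries,
    )
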