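"""Contingency and mean-comparison statistics for group analyses.

Pearson chi-square (no continuity correction), Fisher's exact test for small
counts, the phi effect size in two conventions, and Student / paired /
Welch t tests with Cohen's d.  The nonstandard phi convention divides the
chi-square statistic by the number of *responsive* units (all units outside
the "none" category) rather than the table total; both denominators are
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyResult",
    "MeanComparisonResult",
    "chi_square",
    "fisher_exact",
    "phi_effect",
    "t_tests",
    "cohens_d",
]


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    n_total: int
    #: total count outside the "none" column — the responsive-unit denominator
    n_responsive: int


def chi_square(table, none_col: int | None = -1) -> ContingencyResult:
    """Pearson chi-square on an r×c count table, without Yates correction.

    ``none_col`` marks the column holding non-responsive ("none") counts;
    the responsive total stored on the result excludes it.  Pass
    ``none_col=None`` for tables without such a column (then the responsive
    total equals the grand total).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError(
            "zero row or column marginal; consider fisher_exact for sparse tables"
        )
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    n_total = int(obs.sum())
    if none_col is None:
        n_resp = n_total
    else:
        n_resp = n_total - int(obs[:, none_col].sum())
    return ContingencyResult(
        chi2=float(chi2), df=int(df), p=float(p),
        observed=obs.astype(int), expected=expected,
        n_total=n_total, n_responsive=n_resp,
    )


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p value for a 2×2 table."""
    obs = np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2×2 table")
    return float(sps.fisher_exact(obs, alternative=alternative)[1])


def phi_effect(result: ContingencyResult, denominator: str = "responsive_m") -> float:
    """phi = sqrt(chi2 / m) with m the responsive count or the table total."""
    if denominator == "responsive_m":
        m = result.n_responsive
    elif denominator == "total_N":
        m = result.n_total
    else:
        raise ValueError("denominator must be 'responsive_m' or 'total_N'")
    if m == 0:
        raise ValueError("zero denominator for phi")
    return float(np.sqrt(result.chi2 / m))


@dataclass
class MeanComparisonResult:
    t: float
    df: float
    p: float
    d: float
    mode: str


def cohens_d(x: np.ndarray, y: np.ndarray, mode: str = "independent") -> float:
    """Cohen's d: pooled-SD standardized mean difference (independent/welch)
    or mean difference over the SD of the paired differences (paired)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if mode == "paired":
        diff = x - y
        sd = diff.std(ddof=1)
        return float(diff.mean() / sd) if sd > 0 else 0.0
    n1, n2 = x.size, y.size
    pooled = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    return float((x.mean() - y.mean()) / pooled) if pooled > 0 else 0.0


def t_tests(x, y, mode: str = "independent") -> MeanComparisonResult:
    """Two-sample t test: 'independent' (pooled), 'welch' or 'paired'."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if mode == "independent":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif mode == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    elif mode == "paired":
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        res = sps.ttest_rel(x, y)
        df = x.size - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MeanComparisonResult(
        t=float(res.statistic), df=df, p=float(res.pvalue),
        d=cohens_d(x, y, "paired" if mode == "paired" else "independent"),
        mode=mode,
    )
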