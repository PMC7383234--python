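"""Two-group comparisons of quantitative sensory testing (QST) measures.

Sensory detection, pain-threshold and tolerance outcomes are compared
between a test and a control cohort either from raw measurement vectors or
from the published summary triples (n, mean, SD).  Two-sample t statistics
(pooled-variance Student or Welch) and Mann-Whitney U tests produce
two-sided p-values; outcomes belonging to the same assessment domain form a
family whose size drives a Sidak family-wise correction
``p_adj = 1 - (1 - p)^m``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "t_from_summary",
    "mann_whitney",
    "sidak_adjust",
    "family_adjust",
    "compare_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and standard deviation of one group's outcome."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: float
    p_two_sided: float
    method: str  # "student" | "welch" | "mann_whitney"
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_sidak: float = float("nan")
    family_size: int = 1


def t_from_summary(
    g1: GroupSummary, g2: GroupSummary, method: str = "welch"
) -> ComparisonResult:
    """Two-sample t-test from summary statistics.

    ``student`` pools variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch-Satterthwaite df.  The 95% CI of the mean difference uses the
    same df and standard error as the test.
    """
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    n1, m1, s1 = g1.n, g1.mean, g1.sd
    n2, m2, s2 = g2.n, g2.mean, g2.sd
    if method == "student":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    t = (m1 - m2) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df)) * se
    return ComparisonResult(
        statistic=float(t),
        df=df,
        p_two_sided=p,
        method=method,
        ci_low=float(m1 - m2 - half),
        ci_high=float(m1 - m2 + half),
    )


def mann_whitney(x, y) -> ComparisonResult:
    """Two-sided Mann-Whitney U test on raw vectors.

    Uses the exact null distribution when the combined sample is small
    (<= 20 observations, no ties) and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        statistic=float(res.statistic),
        df=float("nan"),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="mann_whitney",
    )


def sidak_adjust(p: float, family_size: int) -> float:
    """Sidak family-wise adjustment ``1 - (1 - p)^family_size``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(1.0 - (1.0 - p) ** family_size)


def family_adjust(comparisons: pd.DataFrame, p_col: str = "p_two_sided") -> pd.DataFrame:
    """Fill ``p_sidak``/``family_size`` from the ``family`` label column.

    The family size of each row is the number of rows sharing its label;
    the adjustment is rowwise Sidak.  Row order does not affect the result.
    """
    if "family" not in comparisons.columns:
        raise ValueError("comparisons table needs a 'family' column")
    if comparisons["family"].isna().any():
        raise ValueError("every comparison row must carry a family label")
    out = comparisons.copy()
    sizes = out.groupby("family")["family"].transform("size")
    out["family_size"] = sizes.astype(int)
    out["p_sidak"] = [
        sidak_adjust(p, m) for p, m in zip(out[p_col], out["family_size"])
    ]
    return out


def compare_table(table: pd.DataFrame, method: str = "welch") -> pd.DataFrame:
    """Run summary-statistic tests over a table of labelled comparisons.

    Expects columns label, family, n1, mean1, sd1, n2, mean2, sd2; returns
    the table with statistic, df, p_two_sided, CI bounds, family_size and
    p_sidak appended.
    """
    rows = []
    for _, r in table.iterrows():
        res = t_from_summary(
            GroupSummary(int(r["n1"]), float(r["mean1"]), float(r["sd1"])),
            GroupSummary(int(r["n2"]), float(r["mean2"]), float(r["sd2"])),
            method=method,
        )
        rows.append(
            {
                "label": r["label"],
                "family": r["family"],
                "statistic": res.statistic,
                "df": res.df,
                "p_two_sided": res.p_two_sided,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method,
            }
        )
    return family_adjust(pd.DataFrame(rows))
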