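"""Group-comparison statistics: one-way ANOVA with Holm-adjusted pairwise
post-hoc comparisons, and the pooled-variance two-tailed Student's t-test.

The Bonferroni-Holm step-down adjustment controls the family-wise error
rate: raw p-values are sorted ascending, the i-th smallest is multiplied
by (m - i + 1), the sequence is made monotone nondecreasing and capped at
1.  Pairwise comparisons use the pooled-variance Student's t by default
(Welch's correction is available behind a flag).  Errors are reported as
s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "Comparison",
    "StatResult",
    "one_way_anova",
    "holm_adjust",
    "two_sample_t",
]


@dataclass
class GroupTable:
    """Replicate measurements keyed by group label."""

    groups: dict

    def __post_init__(self) -> None:
        self.groups = {str(k): np.asarray(v, dtype=np.float64) for k, v in self.groups.items()}
        for name, vals in self.groups.items():
            if vals.ndim != 1 or len(vals) < 2:
                raise ValueError(f"group {name!r} needs at least 2 replicates")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} contains non-finite values")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, group_col: str = "group", value_col: str = "value") -> "GroupTable":
        return cls({g: sub[value_col].to_numpy() for g, sub in df.groupby(group_col, sort=False)})

    @property
    def names(self) -> list:
        return list(self.groups)

    def sem(self) -> dict:
        return {k: float(sps.sem(v)) for k, v in self.groups.items()}


@dataclass
class Comparison:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple
    pvalue: float
    alpha: float
    comparisons: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": f"{c.group_a} vs {c.group_b}",
                "statistic": c.statistic,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_holm": c.p_adjusted,
                "significant": c.significant,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    The i-th smallest of m p-values is multiplied by (m - i + 1), the
    sequence is made monotone nondecreasing (cumulative maximum) and
    capped at 1.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    stepped = p[order] * np.arange(m, 0, -1)
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float, float]:
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        # Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    else:
        df = len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def one_way_anova(
    table: GroupTable,
    alpha: float = 0.05,
    welch_posthoc: bool = False,
    posthoc: bool = True,
) -> StatResult:
    """Classical one-way ANOVA with Holm-adjusted pairwise post-hoc t-tests.

    F has (k-1, N-k) degrees of freedom.  All pairwise comparisons are
    performed (the comparison set is not restricted), each a two-tailed
    Student's t, then Holm-adjusted as a family.  ``posthoc=False`` skips
    the pairwise tests and reports the omnibus F only.
    """
    names = table.names
    if len(names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [table.groups[n] for n in names]
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group; F undefined")
    f_stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)] if posthoc else []
    raw = []
    stats_df = []
    for i, j in pairs:
        t, df, pr = _pooled_t(arrays[i], arrays[j], welch=welch_posthoc)
        raw.append(pr)
        stats_df.append((t, df))
    adj = holm_adjust(raw) if raw else np.array([])
    comparisons = [
        Comparison(
            group_a=names[i],
            group_b=names[j],
            statistic=stats_df[idx][0],
            df=stats_df[idx][1],
            p_raw=raw[idx],
            p_adjusted=float(adj[idx]),
            significant=bool(adj[idx] < alpha),
        )
        for idx, (i, j) in enumerate(pairs)
    ]
    return StatResult(
        test="one-way ANOVA + Holm post hoc",
        statistic=float(f_stat),
        df=(k - 1, n_total - k),
        pvalue=float(p),
        alpha=alpha,
        comparisons=comparisons,
    )


def two_sample_t(table: GroupTable, tails: int = 2, welch: bool = False, alpha: float = 0.05) -> StatResult:
    """Two-tailed Student's t-test (pooled variance) between two groups."""
    if tails != 2:
        raise ValueError("only the two-tailed test is implemented")
    names = table.names
    if len(names) != 2:
        raise ValueError("two_sample_t needs exactly 2 groups")
    a, b = table.groups[names[0]], table.groups[names[1]]
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        # identical constant groups: no evidence of difference
        return StatResult(
            test="Student's t (pooled)" if not welch else "Welch's t",
            statistic=0.0,
            df=(len(a) + len(b) - 2,),
            pvalue=1.0,
            alpha=alpha,
        )
    t, df, p = _pooled_t(a, b, welch=welch)
    return StatResult(
        test="Student's t (pooled)" if not welch else "Welch's t",
        statistic=t,
        df=(df,),
        pvalue=p,
        alpha=alpha,
        comparisons=[Comparison(names[0], names[1], t, df, p, p, bool(p < alpha))],
    )
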