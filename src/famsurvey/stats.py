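"""Box-plot summaries and two-group t-tests with survey conventions.

Quartiles use linear interpolation (numpy's default, the "type 7" rule);
whiskers extend to the most extreme data points within 1.5 IQR of the box
(Tukey), and notches are median +/- 1.58 IQR / sqrt(n). Two-group
comparisons default to the pooled-variance Student t-test (Welch available
via flag) with the conventional significance flags: p < 0.05 significant,
p < 0.001 highly significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BoxSummary",
    "TTestResult",
    "box_summary",
    "two_group_ttest",
    "pairwise_ttests",
]


@dataclass(frozen=True)
class BoxSummary:
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    notch_low: float
    notch_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    highly_significant: bool
    welch: bool = False
    degenerate: bool = False


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Notched Tukey box-plot statistics for one sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("box_summary needs at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(med)
    whisker_high = float(inside.max()) if inside.size else float(med)
    notch = 1.58 * iqr / np.sqrt(x.size)
    outliers = tuple(sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]))
    return BoxSummary(
        n=int(x.size), mean=float(x.mean()), median=float(med),
        q1=float(q1), q3=float(q3), iqr=float(iqr),
        whisker_low=whisker_low, whisker_high=whisker_high,
        notch_low=float(med - notch), notch_high=float(med + notch),
        outliers=outliers,
    )


def two_group_ttest(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TTestResult:
    """Unpaired two-group t-test; pooled-variance Student by default.

    Degenerate inputs follow the declared conventions: equal constant
    groups give t = 0, p = 1; zero variance with unequal means gives
    p -> 0, flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=a.size + b.size - 2, p=1.0,
                               significant=False, highly_significant=False,
                               welch=welch, degenerate=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(t=float(t), df=a.size + b.size - 2, p=0.0,
                           significant=True, highly_significant=True,
                           welch=welch, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    return TTestResult(t=t, df=df, p=p, significant=p < 0.05,
                       highly_significant=p < 0.001, welch=welch)


def pairwise_ttests(
    groups: Mapping[str, Sequence[float]],
    welch: bool = False,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """All two-group comparisons among named samples, one row per pair.

    Significance flags use the raw p values; a Bonferroni-adjusted column
    is included for transparency only.
    """
    names = [n for n in groups if len(groups[n]) >= 2]
    rows = []
    pairs = list(combinations(names, 2))
    m = len(pairs)
    for ga, gb in pairs:
        r = two_group_ttest(groups[ga], groups[gb], welch=welch)
        row = {
            "group_a": ga, "group_b": gb, "n_a": len(groups[ga]), "n_b": len(groups[gb]),
            "t": r.t, "df": r.df, "p": r.p,
            "significant": r.significant, "highly_significant": r.highly_significant,
        }
        if bonferroni:
            row["p_bonferroni"] = min(r.p * m, 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
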