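"""Paired Pre/Post statistics: exact Wilcoxon signed-rank test and summaries.

With cohorts of half a dozen subjects the normal approximation to the
signed-rank null is meaningless, so the two-sided p-value is computed from
the exact permutation distribution of the rank sum over all 2^m sign
assignments of the observed |difference| multiset (midranks for ties, zero
differences dropped).  The distribution is obtained by exact integer
convolution over the doubled ranks — identical to full enumeration, without
the exponential cost.  Above m = 20 paired observations the test falls back
to the continuity-corrected normal approximation and flags it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

EXACT_LIMIT = 20


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float       # W, sum of ranks of positive differences
    n_used: int            # pairs remaining after dropping zero differences
    method: str            # "exact" | "normal_approx" | "degenerate"
    all_zero: bool = False


@dataclass(frozen=True)
class PairedComparison:
    """Per-index paired summary: medians, quartiles and the exact p-value."""

    index_name: str
    pre: np.ndarray
    post: np.ndarray
    median_pre: float
    q25_pre: float
    q75_pre: float
    median_post: float
    q25_post: float
    q75_post: float
    p_value: float
    test: WilcoxonResult = field(repr=False, default=None)


def _exact_signed_rank_p(d: np.ndarray) -> WilcoxonResult:
    ranks = sstats.rankdata(np.abs(d))          # midranks for ties
    w2 = int(round(2.0 * ranks[d > 0].sum()))   # doubled ranks are integers
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # Exact null distribution of the doubled rank sum by integer convolution:
    # counts[s] = number of sign assignments with doubled positive-rank sum s.
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:  # r >= 2 always (zero differences were dropped)
        counts[r:] = counts[r:] + counts[:-r]
    n_total = 2 ** len(d)
    lower = int(sum(counts[: w2 + 1]))
    upper = int(sum(counts[w2:]))
    p = min(1.0, 2.0 * min(lower, upper) / n_total)
    return WilcoxonResult(p_value=p, statistic=w2 / 2.0, n_used=len(d), method="exact")


def exact_wilcoxon_signed_rank(pre, post) -> WilcoxonResult:
    """Two-sided paired signed-rank test on differences ``post - pre``.

    Zero differences are dropped (the classical exact procedure); ties get
    midranks; the two-sided p doubles the smaller tail including the
    observed statistic, capped at 1.  All differences zero gives p = 1 with
    the ``all_zero`` flag set.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    if len(pre) < 2:
        raise ValueError("paired test needs at least 2 subjects")
    d = post - pre
    d = d[d != 0]
    if len(d) == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n_used=0,
                              method="degenerate", all_zero=True)
    if len(d) <= EXACT_LIMIT:
        return _exact_signed_rank_p(d)
    res = sstats.wilcoxon(d, alternative="two-sided", correction=True,
                          method="approx")
    return WilcoxonResult(p_value=float(res.pvalue), statistic=float(res.statistic),
                          n_used=len(d), method="normal_approx")


def summarize(values) -> tuple[float, float, float, float]:
    """Median, 25th and 75th percentiles (linear interpolation) and IQR."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("summarize needs at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q25), float(q75), float(q75 - q25)


def compare_paired(index_name: str, pre, post) -> PairedComparison:
    """Build the per-index Pre/Post comparison record."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    med_a, q25_a, q75_a, _ = summarize(pre)
    med_b, q25_b, q75_b, _ = summarize(post)
    test = exact_wilcoxon_signed_rank(pre, post)
    return PairedComparison(
        index_name=index_name, pre=pre, post=post,
        median_pre=med_a, q25_pre=q25_a, q75_pre=q75_a,
        median_post=med_b, q25_post=q25_b, q75_post=q75_b,
        p_value=test.p_value, test=test,
    )


def _cell(values, med, q25, q75, decimals: int, spread: str) -> str:
    if spread == "range":
        lo, hi = float(np.min(values)), float(np.max(values))
    else:
        lo, hi = q25, q75
    f = f"{{:.{decimals}f}}"
    return f"{f.format(med)} ({f.format(lo)}–{f.format(hi)})"


def results_table(
    comparisons: list[PairedComparison],
    units: dict[str, str] | None = None,
    decimals: int = 2,
    spread: str = "iqr",
) -> pd.DataFrame:
    """Render comparisons as a results table.

    One row per index with ``median (q25-q75)`` cells (or ``(min-max)`` with
    ``spread='range'``), the exact p-value, and a ``*`` marker for p < 0.05.
    """
    if not comparisons:
        raise ValueError("results_table needs at least one comparison")
    if spread not in ("iqr", "range"):
        raise ValueError("spread must be 'iqr' or 'range'")
    units = units or {}
    rows = []
    for c in comparisons:
        marker = "*" if c.p_value < 0.05 else ""
        rows.append({
            "Indices": c.index_name,
            "Units": units.get(c.index_name, ""),
            "Pre": _cell(c.pre, c.median_pre, c.q25_pre, c.q75_pre, decimals, spread),
            "Post": _cell(c.post, c.median_post, c.q25_post, c.q75_post, decimals, spread),
            "p value": f"{c.p_value:.3g}{marker}",
        })
    return pd.DataFrame(rows, columns=["Indices", "Units", "Pre", "Post", "p value"])


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the results table."""
    return table.to_string(index=False)
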