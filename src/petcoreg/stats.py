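"""Paired agreement statistics: Wilcoxon signed-rank, Bland-Altman, summaries.

The Wilcoxon test is two-sided; zero differences are dropped (Wilcoxon's
original treatment) and tied absolute differences receive average ranks.
For n <= 12 the p value is exact, computed from the full null distribution of
the positive-rank sum via the shift (convolution) algorithm; larger samples
use the normal approximation with tie correction and continuity correction.

Bland-Altman agreement reports the mean difference, the sample SD of the
differences (n-1 denominator) and the 95 % limits of agreement
mean ± 1.96 SD; mean ± 2 SD is reported alongside for plot annotation.
Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "BlandAltman",
    "bland_altman",
    "summarize_deviations",
    "bland_altman_plot",
    "deviation_boxplot",
]


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float        # sum of positive ranks (after dropping zeros)
    n_used: int             # pairs remaining after dropping zero differences
    exact: bool
    all_zero: bool = False
    significant: bool = False  # at the conventional 0.05 level


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    # Shift algorithm over doubled ranks (average ranks are multiples of 0.5).
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_lo = dist[: w2 + 1].sum()
    p_hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def wilcoxon_signed_rank(differences, exact_max_n: int = 12) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of paired differences against zero."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences provided")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, True, all_zero=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
        return WilcoxonResult(p, w_plus, n, True, significant=p < 0.05)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(1.0, w_plus, n, False)
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var) if delta != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(p, w_plus, n, False, significant=p < 0.05)


@dataclass(frozen=True)
class BlandAltman:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float           # mean - 1.96 SD (95 % limits of agreement)
    loa_high: float          # mean + 1.96 SD
    loa2_low: float          # mean - 2 SD (plot annotation convention)
    loa2_high: float


def bland_altman(a, b) -> BlandAltman:
    """Agreement of paired measurements; differences are ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        n=a.size,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        loa2_low=mean - 2.0 * sd,
        loa2_high=mean + 2.0 * sd,
    )


_QUANTITIES = {
    "suvmax": "d_suvmax_pct",
    "mtv": "d_mtv_pct",
    "tlg": "d_tlg_pct",
}


def summarize_deviations(
    records: pd.DataFrame, by: tuple[str, ...] = ("grid", "mode", "method")
) -> pd.DataFrame:
    """Descriptive + agreement summary of deviation records per group.

    For each group and each of SUVmax/MTV/TLG the signed and unsigned
    relative differences (%) are summarized (mean, median, IQR, range), with
    a two-sided Wilcoxon p against zero and Bland-Altman mean/SD/95 % LoA of
    the signed differences.  Empty input raises; groups appear in sorted key
    order for reproducible output.
    """
    if records.empty:
        raise ValueError("no deviation records to summarize")
    rows = []
    for keys, grp in records.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for quantity, col in _QUANTITIES.items():
            d = grp[col].to_numpy(dtype=float)
            if d.size == 0:
                continue
            ad = np.abs(d)
            w = wilcoxon_signed_rank(d)
            row = dict(zip(by, keys))
            row.update(
                quantity=quantity,
                n=d.size,
                mean=d.mean(),
                median=float(np.median(d)),
                q1=float(np.quantile(d, 0.25)),
                q3=float(np.quantile(d, 0.75)),
                min=d.min(),
                max=d.max(),
                abs_mean=ad.mean(),
                abs_median=float(np.median(ad)),
                abs_q1=float(np.quantile(ad, 0.25)),
                abs_q3=float(np.quantile(ad, 0.75)),
                abs_min=ad.min(),
                abs_max=ad.max(),
                wilcoxon_p=w.p_value,
            )
            if d.size >= 2:
                ba = bland_altman(d, np.zeros_like(d))
                row.update(
                    ba_mean=ba.mean_diff,
                    ba_sd=ba.sd_diff,
                    loa_low=ba.loa_low,
                    loa_high=ba.loa_high,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def bland_altman_plot(a, b, ax=None, label: str = ""):
    """Classic Bland-Altman plot: pair means vs differences with LoA lines.

    Solid line: mean difference; dashed: mean ± 2 SD; dotted: 95 % LoA
    (mean ± 1.96 SD).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(ba.mean_diff, color="k", lw=1.2)
    for y in (ba.loa2_low, ba.loa2_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if label:
        ax.set_title(label)
    return ax


def deviation_boxplot(records: pd.DataFrame, quantity: str, ax=None, unsigned: bool = True):
    """Box plots of relative changes per (grid, mode) group for one quantity."""
    import matplotlib.pyplot as plt

    col = _QUANTITIES[quantity]
    if ax is None:
        _, ax = plt.subplots()
    groups, data = [], []
    for keys, grp in records.groupby(["grid", "mode"], sort=True):
        groups.append("/".join(str(k) for k in keys))
        vals = grp[col].to_numpy(dtype=float)
        data.append(np.abs(vals) if unsigned else vals)
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(("unsigned " if unsigned else "") + f"relative {quantity} change (%)")
    return ax
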