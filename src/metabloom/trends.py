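"""Rank correlations and monotonic-trend tests for the monitoring series.

Spearman rank correlation (depth of the population maximum versus the
candidate physical depths), the seasonal Mann–Kendall (SMK) test for a
monotonic trend in depth-integrated biomass, and ordinary least-squares
linear trends of annual extremes.

The SMK statistic is the sum over seasonal blocks of the Kendall S
statistic computed on each season's yearly values; its variance is the sum
of the tie-corrected per-season variances, tau is ΣS normalised by the
summed pair counts, and the two-sided p-value uses the normal
approximation with continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "TrendResult",
    "spearman",
    "seasonal_mann_kendall",
    "linear_trend",
]


@dataclass
class CorrelationResult:
    variable_pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


@dataclass
class TrendResult:
    statistic: float       # tau for SMK, slope for OLS
    p_value: float
    n: int                 # seasons used (SMK) or years (OLS)
    method: str            # "smk" | "ols"
    s: float | None = None  # summed Kendall S (SMK only)
    r2: float | None = None  # OLS only


def spearman(
    x, y, names: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rank-order correlation with average ranks for ties.

    Pairs with an absent member are dropped; the p-value uses the
    large-sample t approximation.
    """
    xs = pd.Series(np.asarray(x, dtype=float))
    ys = pd.Series(np.asarray(y, dtype=float))
    ok = xs.notna() & ys.notna()
    xv, yv = xs[ok].to_numpy(), ys[ok].to_numpy()
    if xv.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(xv, yv)
    return CorrelationResult(names, float(rho), float(p), int(xv.size))


def _kendall_s(values: np.ndarray) -> tuple[int, float, int]:
    """Kendall S, tie-corrected variance contribution and pair count for
    one season's year-ordered values."""
    v = np.asarray(values, dtype=float)
    n = v.size
    s = 0
    for i in range(n - 1):
        s += int(np.sign(v[i + 1 :] - v[i]).sum())
    _, counts = np.unique(v, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var, n * (n - 1) // 2


def seasonal_mann_kendall(
    series: pd.Series, season_of=None
) -> TrendResult:
    """Seasonal Mann–Kendall trend test on a timestamp-indexed series.

    ``season_of`` maps a timestamp to a season label (default: calendar
    month, the standard blocking for biweekly environmental series).
    Within each season, values are averaged per year and ordered by year;
    seasons with fewer than 3 yearly values are skipped.  Missing seasons
    (observation gaps) are simply absent.
    """
    if season_of is None:
        season_of = lambda t: t.month  # noqa: E731
    s = series.dropna().sort_index()
    if s.empty:
        raise ValueError("empty series")
    seasons = pd.Series([season_of(t) for t in s.index], index=s.index)
    years = pd.Series(s.index.year, index=s.index)
    grouped = s.groupby([seasons, years]).mean()
    total_s = 0
    total_var = 0.0
    total_pairs = 0
    n_seasons = 0
    for sea in grouped.index.get_level_values(0).unique():
        vals = grouped.loc[sea].sort_index().to_numpy()
        if vals.size < 3:
            continue
        sk, var, pairs = _kendall_s(vals)
        total_s += sk
        total_var += var
        total_pairs += pairs
        n_seasons += 1
    if n_seasons == 0:
        raise ValueError("no season has at least 3 yearly values")
    tau = total_s / total_pairs if total_pairs else 0.0
    if total_var <= 0:
        return TrendResult(0.0, 1.0, n_seasons, "smk", s=float(total_s))
    if total_s > 0:
        z = (total_s - 1) / math.sqrt(total_var)
    elif total_s < 0:
        z = (total_s + 1) / math.sqrt(total_var)
    else:
        z = 0.0
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return TrendResult(float(tau), float(p), n_seasons, "smk", s=float(total_s))


def linear_trend(years, values) -> TrendResult:
    """OLS linear trend of yearly values: slope, r², two-sided p."""
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 years")
    if np.all(x == x[0]):
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return TrendResult(
        float(res.slope), float(res.pvalue), int(x.size), "ols",
        r2=float(res.rvalue**2),
    )
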