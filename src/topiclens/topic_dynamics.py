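"""Per-year topic prevalence and hot/cold trend classification.

Each article is assigned its *dominant* topic (arg-max of its θ row) and a
topic's prevalence in year y is the share of that year's articles dominated
by it.  Two tests are run per topic against calendar year: ordinary least
squares of the share (slope and its two-sided t-test) and the
Cochran-Armitage trend test on the underlying binomial counts.  A topic is
*hot* when its share rises significantly, *cold* when it falls, *infrequent*
when its mean share is below a floor, else *stable*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "YearlyShareSeries",
    "TrendResult",
    "dominant_topic",
    "yearly_share",
    "linear_trend",
    "cochran_armitage",
    "classify_trend",
    "trend_table",
]


@dataclass
class YearlyShareSeries:
    """Per-year per-topic prevalence: counts x (Y × K), year totals n (Y),
    and shares x/n (rows sum to 1)."""

    years: np.ndarray        # (Y,) ordered ascending
    x: np.ndarray            # (Y, K) articles of year y dominated by topic k
    n: np.ndarray            # (Y,)  articles in year y

    @property
    def share(self) -> np.ndarray:
        return self.x / self.n[:, None]

    @property
    def n_topics(self) -> int:
        return self.x.shape[1]


@dataclass
class TrendResult:
    """Trend statistics for one topic's yearly share series."""

    slope: float
    slope_p: float
    ca_z: float
    ca_p: float
    mean_share: float
    label: str = ""


def dominant_topic(theta: np.ndarray) -> np.ndarray:
    """Arg-max topic per document; ties resolved to the lower topic index."""
    return np.argmax(theta, axis=1)


def yearly_share(dominant: np.ndarray, doc_years: np.ndarray,
                 n_topics: int | None = None) -> YearlyShareSeries:
    """Count dominant-topic articles per (year, topic) and form shares."""
    dominant = np.asarray(dominant)
    doc_years = np.asarray(doc_years)
    if dominant.size == 0:
        raise ValueError("no documents")
    if n_topics is None:
        n_topics = int(dominant.max()) + 1
    years = np.array(sorted(set(doc_years.tolist())), dtype=np.int64)
    x = np.zeros((len(years), n_topics), dtype=np.int64)
    for yi, y in enumerate(years):
        mask = doc_years == y
        x[yi] = np.bincount(dominant[mask], minlength=n_topics)
    return YearlyShareSeries(years=years, x=x, n=x.sum(axis=1))


def mean_theta_share(theta: np.ndarray, doc_years: np.ndarray) -> pd.DataFrame:
    """Alternative prevalence: mean θ mass per year (year × topic frame).

    Provided for users preferring soft topic mass over dominant-topic
    counts; the trend tests operate on the count-based series.
    """
    frame = pd.DataFrame(theta)
    frame["year"] = np.asarray(doc_years)
    return frame.groupby("year").mean()


def linear_trend(years: np.ndarray, shares: np.ndarray) -> tuple[float, float]:
    """OLS slope of share on calendar year with its two-sided p-value.

    Requires at least 3 years.  A numerically exact fit (zero residual)
    returns p = 0.
    """
    years = np.asarray(years, dtype=np.float64)
    shares = np.asarray(shares, dtype=np.float64)
    if len(years) < 3:
        raise ValueError(f"need >= 3 years for a trend, got {len(years)}")
    if np.allclose(shares, shares[0]):
        return 0.0, 1.0
    res = stats.linregress(years, shares)
    p = float(res.pvalue)
    if not np.isfinite(p):  # perfect linear fit → zero stderr
        p = 0.0
    return float(res.slope), p


def cochran_armitage(x: np.ndarray, n: np.ndarray,
                     scores: np.ndarray | None = None) -> tuple[float, float]:
    """Cochran-Armitage trend test for binomial proportions over ordered groups.

    With pooled proportion p̄ = Σx/Σn and group scores s (default: the group
    index; calendar years are the natural choice),

        T      = Σ_y s_y (x_y − n_y p̄)
        Var(T) = p̄(1−p̄) [Σ n_y s_y² − (Σ n_y s_y)²/Σn]

    and z = T/√Var(T) is compared with the standard normal (two-sided).  The
    statistic is invariant to affine rescaling of the scores.  A degenerate
    table (p̄ of 0 or 1, no variation) returns z = 0, p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if np.any(x > n) or np.any(x < 0):
        raise ValueError("need 0 <= x[y] <= n[y] for every year")
    if np.count_nonzero(n) < 2:
        raise ValueError("need at least 2 years with observations")
    if scores is None:
        scores = np.arange(len(x), dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)

    N = n.sum()
    p_bar = x.sum() / N
    if p_bar in (0.0, 1.0):
        return 0.0, 1.0
    t_stat = float(np.sum(scores * (x - n * p_bar)))
    var = p_bar * (1 - p_bar) * (np.sum(n * scores**2) - np.sum(n * scores) ** 2 / N)
    z = t_stat / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def classify_trend(result: TrendResult, infrequent_threshold: float = 0.04,
                   alpha: float = 0.05) -> str:
    """Label a topic hot / cold / infrequent / stable.

    Infrequent topics (mean share below the floor) are set aside first;
    among the rest, a significant Cochran-Armitage trend with positive OLS
    slope is *hot*, with negative slope *cold*.
    """
    if result.mean_share < infrequent_threshold:
        return "infrequent"
    if result.ca_p < alpha:
        if result.slope > 0:
            return "hot"
        if result.slope < 0:
            return "cold"
    return "stable"


def trend_table(series: YearlyShareSeries, infrequent_threshold: float = 0.04,
                alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
    """Per-topic trend statistics and labels as a tidy frame.

    ``bonferroni`` divides the significance level by the number of topics
    (no correction by default).
    """
    level = alpha / series.n_topics if bonferroni else alpha
    share = series.share
    rows = []
    for k in range(series.n_topics):
        slope, slope_p = linear_trend(series.years, share[:, k])
        ca_z, ca_p = cochran_armitage(series.x[:, k], series.n,
                                      scores=series.years.astype(np.float64))
        res = TrendResult(slope=slope, slope_p=slope_p, ca_z=ca_z, ca_p=ca_p,
                          mean_share=float(share[:, k].mean()))
        res.label = classify_trend(res, infrequent_threshold, level)
        rows.append(
            {"topic": k, "slope": res.slope, "slope_p": res.slope_p,
             "ca_z": res.ca_z, "ca_p": res.ca_p,
             "mean_share": res.mean_share, "label": res.label}
        )
    return pd.DataFrame(rows)
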