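"""The heat attention index and its association with temperature.

The index normalises heat-related post volume for economic development:
for region i, N = N_i / gdp_i at whole-period resolution and
T = N_ij / gdp_i at region-day resolution, with gdp_i the per-capita GDP in
ten-thousand-yuan units. Dividing by per-capita GDP discounts the higher
posting volume of wealthier, more urbanised, better-connected regions, so
the index tracks perception rather than platform penetration.
"""
from __future__ import annotations

import datetime as dt
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .records import AttentionRecord, PostRecord


def attention_index(n_posts: int, gdp: float) -> float:
    """Posts divided by per-capita GDP (ten-thousand-yuan units)."""
    if gdp <= 0:
        raise ValueError(f"per-capita GDP must be positive, got {gdp}")
    return n_posts / gdp


def daily_attention(
    posts: Iterable[PostRecord],
    regions: Mapping[str, float],
    date_start: dt.date | None = None,
    date_end: dt.date | None = None,
    drop_zero_days: bool = False,
) -> list[AttentionRecord]:
    """Region-day attention records over the study window.

    Every region in ``regions`` gets a record for every day of the window
    (zero-post days included with index 0 — they are informative about the
    cold limb of the attention curve — unless ``drop_zero_days``). The window
    defaults to the posts' date span. A post whose region has no GDP entry is
    an error.
    """
    posts = list(posts)
    missing = sorted({p.region for p in posts} - set(regions))
    if missing:
        raise ValueError(f"regions without GDP metadata: {missing}")
    if date_start is None or date_end is None:
        if not posts:
            raise ValueError("cannot infer a study window from an empty post set")
        dates = [p.date for p in posts]
        date_start = date_start or min(dates)
        date_end = date_end or max(dates)

    counts = Counter((p.region, p.date) for p in posts)
    out: list[AttentionRecord] = []
    n_days = (date_end - date_start).days + 1
    for region in sorted(regions):
        gdp = regions[region]
        for i in range(n_days):
            date = date_start + dt.timedelta(days=i)
            n = counts.get((region, date), 0)
            if n == 0 and drop_zero_days:
                continue
            out.append(
                AttentionRecord(
                    region=region, date=date, n_posts=n, gdp=gdp,
                    index=attention_index(n, gdp),
                )
            )
    return out


def period_attention(
    posts: Iterable[PostRecord], regions: Mapping[str, float]
) -> list[AttentionRecord]:
    """Whole-period attention per region (date marker ``None``)."""
    posts = list(posts)
    missing = sorted({p.region for p in posts} - set(regions))
    if missing:
        raise ValueError(f"regions without GDP metadata: {missing}")
    counts = Counter(p.region for p in posts)
    return [
        AttentionRecord(
            region=region, date=None, n_posts=counts.get(region, 0),
            gdp=regions[region],
            index=attention_index(counts.get(region, 0), regions[region]),
        )
        for region in sorted(regions)
    ]


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p
    from the large-sample t approximation.

    Constant input is an error (the correlation is undefined), as is n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation is undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
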