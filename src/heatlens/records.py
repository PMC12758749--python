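"""Core record types shared across the pipeline stages.

These are deliberately plain dataclasses: each one is a single row of one of
the pipeline's tabular interchange formats (posts JSONL, GSOD-dialect CSV,
region-day temperature CSV, attention CSV), so round-tripping through disk is
loss-free and every stage can be exercised on in-memory lists in tests.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field


@dataclass
class PostRecord:
    """One short-text post: the unit of the heat-related corpus.

    ``tokens`` stays empty until the post has been segmented; ``raw_text``
    always keeps the text as received (cleaning produces a new record).
    """

    post_id: str
    date: dt.date
    region: str
    raw_text: str
    tokens: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StationRecord:
    """One station-day of a daily weather summary; ``tmax_f`` is the daily
    maximum temperature in °F, ``None`` when the station did not report."""

    station: str
    date: dt.date
    tmax_f: float | None


@dataclass(frozen=True)
class RegionDayTemp:
    """Regional daily maximum temperature in °C: the unweighted mean of the
    non-missing station maxima in the region on that day."""

    region: str
    date: dt.date
    tmax_c: float
    n_stations: int


@dataclass(frozen=True)
class AttentionRecord:
    """Heat attention for one region (``date is None``: whole study period)
    or one region-day: post count divided by per-capita GDP.

    GDP is in units of ten thousand yuan, so the index is "posts per
    ten-thousand-yuan of per-capita GDP" — a volume measure normalised for
    economic development.
    """

    region: str
    date: dt.date | None
    n_posts: int
    gdp: float
    index: float
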