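"""Seeded synthetic worlds for end-to-end testing of the heat-perception
pipeline.

A world is a set of regions, each with a per-capita GDP (ten-thousand-yuan
units), a handful of weather stations, and a generative attention law: the
expected number of heat-related posts on a day with regional daily maximum
temperature ω (°C) is

    E[N] = gdp · max(a0 + a1·ω + a2·ω², floor)

so that the attention index N/gdp is an unbiased estimate of the quadratic
attention–temperature curve the perception stage tries to recover. Post
counts are Poisson (counts are nonnegative integers and the Poisson mean
matches the quadratic law exactly); the rate floor keeps the Poisson rate
positive where a fitted-down-to-zero quadratic would go negative.

Station temperatures follow seasonal-sinusoid + AR(1) + Gaussian-noise
processes and are emitted in °F in the GSOD dialect, so the reader path is
exercised. Post texts are drawn from a known LDA generative model over an
abstract vocabulary (document-topic mixture from a symmetric Dirichlet,
token topics, tokens from per-topic word distributions); a few heat-keyword
tokens receive mass in every topic so that keyword filtering — the way the
real corpus was collected — can be emulated.

Randomness: one seed per world; per-region (and per-station) substreams are
derived from it with ``numpy.random.SeedSequence`` spawn keys, so a region's
draws do not shift when unrelated parts of the config change.
"""
from __future__ import annotations

import datetime as dt
import json
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .records import PostRecord, RegionDayTemp, StationRecord

#: Heat-keyword tokens given mass in every synthetic topic, so keyword
#: filtering retains a (region-independent) fraction of synthetic posts.
SYNTHETIC_KEYWORDS = ("hot", "sweating", "scorching", "heatstroke")


@dataclass
class WorldConfig:
    """Full description of a synthetic world.

    ``attention_params[i]`` is the generative quadratic (a0, a1, a2) of
    region i — attention index per °C and °C²; ``gdp_per_capita`` is in
    ten-thousand-yuan units. Temperature parameters are in °C.
    """

    n_regions: int = 10
    stations_per_region: int = 3
    date_start: dt.date = dt.date(2023, 7, 1)
    date_end: dt.date = dt.date(2023, 8, 31)
    gdp_per_capita: tuple[float, ...] = ()
    temp_mean: float | tuple[float, ...] = 29.0
    temp_amplitude: float = 3.0
    temp_ar1: float = 0.6
    temp_noise_sd: float = 1.5
    attention_params: tuple[tuple[float, float, float], ...] = ()
    topic_word_dists: np.ndarray | None = None
    vocabulary: tuple[str, ...] = ()
    doc_topic_alpha: float = 0.1
    doc_length_mean: float = 12.0
    rate_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValueError(
                f"empty date range: date_start {self.date_start} is after "
                f"date_end {self.date_end}"
            )
        if self.topic_word_dists is not None:
            phi = np.asarray(self.topic_word_dists, dtype=float)
            if phi.ndim != 2 or phi.shape[0] < 1:
                raise ValueError("topic_word_dists must be a (K, V) matrix with K >= 1")
            if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("each topic-word distribution must sum to 1")
            self.topic_word_dists = phi

    @property
    def regions(self) -> list[str]:
        return [f"R{i:02d}" for i in range(self.n_regions)]

    @property
    def dates(self) -> list[dt.date]:
        n = (self.date_end - self.date_start).days + 1
        return [self.date_start + dt.timedelta(days=i) for i in range(n)]


def default_topics(k: int = 4, words_per_topic: int = 10) -> tuple[np.ndarray, tuple[str, ...]]:
    """K topics over an abstract vocabulary: each topic puts 90% of its mass
    on its own block of words and 10% on the shared heat keywords."""
    vocab: list[str] = []
    for t in range(k):
        vocab.extend(f"t{t}w{j:02d}" for j in range(words_per_topic))
    vocab.extend(SYNTHETIC_KEYWORDS)
    v = len(vocab)
    phi = np.zeros((k, v))
    for t in range(k):
        phi[t, t * words_per_topic : (t + 1) * words_per_topic] = 0.9 / words_per_topic
        phi[t, k * words_per_topic :] = 0.1 / len(SYNTHETIC_KEYWORDS)
    return phi, tuple(vocab)


def default_world(seed: int = 0, n_regions: int = 10) -> WorldConfig:
    """The reference study conditions: a 62-day peak-summer window, regions
    whose generative vertex temperatures span 24–34 °C, curvature (heat
    sensitivity) spanning the range seen across real provinces, and
    per-capita GDP spanning 3–13 ten-thousand-yuan. Under these settings a
    world emits roughly 5×10⁴ heat-related posts — the scale of a real
    peak-summer microblog crawl."""
    vertices = np.linspace(24.0, 34.0, n_regions)
    curvatures = np.linspace(0.1, 1.0, n_regions)
    base = 0.5  # attention-index value at the vertex (comfort-point floor)
    params = tuple(
        (float(a2 * v * v + base), float(-2.0 * a2 * v), float(a2))
        for v, a2 in zip(vertices, curvatures)
    )
    gdp = tuple(float(g) for g in np.linspace(3.0, 13.0, n_regions))
    phi, vocab = default_topics()
    return WorldConfig(
        n_regions=n_regions,
        gdp_per_capita=gdp,
        attention_params=params,
        topic_word_dists=phi,
        vocabulary=vocab,
        seed=seed,
    )


def generative_vertices(config: WorldConfig) -> list[float]:
    """Vertex temperature −a1/(2·a2) of each region's generative quadratic."""
    return [-a1 / (2.0 * a2) for (_, a1, a2) in config.attention_params]


def _station_rng(config: WorldConfig, region_idx: int, station_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, region_idx, station_idx))
    )


def _region_rng(config: WorldConfig, region_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, region_idx))
    )


def simulate_temperatures(config: WorldConfig) -> list[StationRecord]:
    """Simulate daily maximum temperatures for every station.

    ω_t = mean + amplitude·sin(2π·dayofyear/365) + r_t with
    r_t = ar1·r_{t−1} + N(0, noise_sd²), r_0 drawn from the stationary
    distribution. Values are emitted in °F (GSOD convention).
    """
    from .meteo import c_to_f

    dates = config.dates
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal_shape = config.temp_amplitude * np.sin(2.0 * np.pi * doy / 365.0)
    means = (
        [float(config.temp_mean)] * config.n_regions
        if np.isscalar(config.temp_mean)
        else [float(m) for m in config.temp_mean]
    )

    records: list[StationRecord] = []
    for ri, region in enumerate(config.regions):
        seasonal = means[ri] + seasonal_shape
        for si in range(config.stations_per_region):
            rng = _station_rng(config, ri, si)
            resid = np.zeros(len(dates))
            if config.temp_noise_sd > 0:
                stat_sd = config.temp_noise_sd / math.sqrt(
                    max(1.0 - config.temp_ar1**2, 1e-12)
                )
                prev = rng.normal(0.0, stat_sd)
                for t in range(len(dates)):
                    prev = config.temp_ar1 * prev + rng.normal(0.0, config.temp_noise_sd)
                    resid[t] = prev
            temps_c = seasonal + resid
            station = f"{region}-S{si}"
            for date, tc in zip(dates, temps_c):
                records.append(
                    StationRecord(station=station, date=date, tmax_f=c_to_f(float(tc)))
                )
    return records


def station_region_map(config: WorldConfig) -> dict[str, str]:
    return {
        f"{region}-S{si}": region
        for region in config.regions
        for si in range(config.stations_per_region)
    }


def expected_attention(config: WorldConfig, region_idx: int, omega: float) -> float:
    """The generative mean attention index at temperature ω (with floor)."""
    a0, a1, a2 = config.attention_params[region_idx]
    return max(a0 + a1 * omega + a2 * omega * omega, config.rate_floor)


def simulate_post_counts(
    config: WorldConfig, temps: Iterable[RegionDayTemp]
) -> dict[tuple[str, dt.date], int]:
    """Draw the Poisson post count for every region-day.

    Rate λ = gdp_i · max(a0 + a1ω + a2ω², floor), so the attention index
    N/gdp has expectation equal to the (floored) generative quadratic.
    """
    if config.rate_floor <= 0:
        raise ValueError("rate_floor must be positive (Poisson rate must be > 0)")
    by_key = {(t.region, t.date): t.tmax_c for t in temps}
    regions = config.regions
    dates = config.dates
    missing = [
        (r, d) for r in regions for d in dates if (r, d) not in by_key
    ]
    if missing:
        raise ValueError(
            f"temperatures do not cover every region-day; first missing: {missing[0]}"
        )
    counts: dict[tuple[str, dt.date], int] = {}
    for ri, region in enumerate(regions):
        rng = _region_rng(config, ri)
        gdp = config.gdp_per_capita[ri]
        for date in dates:
            lam = gdp * expected_attention(config, ri, by_key[(region, date)])
            counts[(region, date)] = int(rng.poisson(lam))
    return counts


def _draw_document(
    rng: np.random.Generator,
    phi_cum: np.ndarray,
    alpha: float,
    length_mean: float,
    theta: np.ndarray | None = None,
) -> list[int]:
    k = phi_cum.shape[0]
    if theta is None:
        theta = rng.dirichlet(np.full(k, alpha))
    length = max(1, int(rng.poisson(length_mean)))
    zs = rng.choice(k, size=length, p=theta)
    us = rng.random(length)
    return [int(np.searchsorted(phi_cum[z], u)) for z, u in zip(zs, us)]


def simulate_posts(
    config: WorldConfig, temps: Iterable[RegionDayTemp]
) -> list[PostRecord]:
    """Simulate the full post corpus for a world.

    Per region-day the post count is Poisson (see
    :func:`simulate_post_counts`); each post's tokens are drawn from the LDA
    generative process with the world's topic-word distributions.
    """
    if config.topic_word_dists is None or not config.vocabulary:
        raise ValueError("config must carry topic_word_dists and a vocabulary")
    temps = list(temps)
    counts = simulate_post_counts(config, temps)
    phi = np.asarray(config.topic_word_dists)
    phi_cum = np.cumsum(phi, axis=1)
    phi_cum[:, -1] = 1.0  # guard against <1 from roundoff
    vocab = config.vocabulary

    posts: list[PostRecord] = []
    for ri, region in enumerate(config.regions):
        # separate stream keeps text draws independent of the count draws
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(2, ri))
        )
        for date in config.dates:
            n = counts[(region, date)]
            for j in range(n):
                word_ids = _draw_document(
                    rng, phi_cum, config.doc_topic_alpha, config.doc_length_mean
                )
                text = " ".join(vocab[w] for w in word_ids)
                posts.append(
                    PostRecord(
                        post_id=f"{region}-{date.isoformat()}-{j:04d}",
                        date=date,
                        region=region,
                        raw_text=text,
                    )
                )
    return posts


def simulate_corpus_docs(
    topic_word_dists: np.ndarray,
    n_docs: int,
    doc_length_mean: float = 12.0,
    seed: int = 0,
    doc_topic_alpha: float = 0.1,
    dominant_profile: Sequence[float] | None = None,
    purity: float = 0.9,
) -> tuple[list[list[int]], list[int]]:
    """Draw a bare LDA corpus (token-id documents) with known structure.

    With ``dominant_profile`` given, dominant topics are apportioned across
    documents in exact proportion (largest-remainder rule) and each document
    mixes ``purity`` of its dominant topic with the rest spread uniformly;
    otherwise mixtures come from a symmetric Dirichlet. Returns the documents
    and each document's generative dominant topic (argmax of its mixture).
    """
    phi = np.asarray(topic_word_dists, dtype=float)
    k = phi.shape[0]
    phi_cum = np.cumsum(phi, axis=1)
    phi_cum[:, -1] = 1.0
    rng = np.random.default_rng(seed)

    dominants: list[int]
    if dominant_profile is not None:
        profile = np.asarray(dominant_profile, dtype=float)
        profile = profile / profile.sum()
        quota = profile * n_docs
        base = np.floor(quota).astype(int)
        rem = n_docs - base.sum()
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
        dominants = [t for t, c in enumerate(base) for _ in range(c)]
        rng.shuffle(dominants)
    else:
        dominants = []

    docs: list[list[int]] = []
    true_dominant: list[int] = []
    for d in range(n_docs):
        if dominant_profile is not None:
            theta = np.full(k, (1.0 - purity) / max(k - 1, 1))
            theta[dominants[d]] = purity
            if k == 1:
                theta = np.ones(1)
        else:
            theta = rng.dirichlet(np.full(k, doc_topic_alpha))
        docs.append(_draw_document(rng, phi_cum, doc_topic_alpha, doc_length_mean, theta))
        true_dominant.append(int(np.argmax(theta)))
    return docs, true_dominant


# ---------------------------------------------------------------------------
# writers: the on-disk interchange formats the pipeline stages read


def write_posts_jsonl(posts: Iterable[PostRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "post_id": p.post_id,
                        "date": p.date.isoformat(),
                        "region": p.region,
                        "text": p.raw_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_posts_jsonl(path) -> list[PostRecord]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            posts.append(
                PostRecord(
                    post_id=str(obj["post_id"]),
                    date=dt.date.fromisoformat(obj["date"]),
                    region=str(obj["region"]),
                    raw_text=str(obj["text"]),
                    tokens=list(obj.get("tokens", [])),
                )
            )
    return posts


def write_regions_csv(config: WorldConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region,gdp_wan_yuan\n")
        for region, gdp in zip(config.regions, config.gdp_per_capita):
            fh.write(f"{region},{gdp!r}\n")


def write_station_map_csv(config: WorldConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("station,region\n")
        for station, region in station_region_map(config).items():
            fh.write(f"{station},{region}\n")
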