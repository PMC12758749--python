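"""End-to-end orchestration: simulate → preprocess → topics → meteo →
attention → perceive, as one seeded, configured, logged run.

Every run writes the full table set plus a JSON manifest recording the
config hash, seed, per-stage row counts and wall times, and the post
conservation balance (posts in = retained + dropped by the keyword filter +
dropped empty). Identical config and seed reproduce identical output
tables.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attention as attn
from . import lda, meteo, perception, synthetic, text_prep
from .records import PostRecord

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    With ``simulate`` true the input files are generated into
    ``out_dir/inputs`` from a seeded synthetic world; otherwise the four
    input paths must point at existing files. CLI flags override file
    values; file values override defaults.
    """

    out_dir: str = "heatlens_run"
    seed: int = 0
    simulate: bool = True
    n_regions: int = 10
    posts_path: str | None = None
    gsod_path: str | None = None
    regions_path: str | None = None
    station_map_path: str | None = None
    stopword_paths: list[str] = field(default_factory=list)
    keywords: list[str] | None = None
    date_start: str | None = None
    date_end: str | None = None
    K: int = 4
    alpha: float = 0.1
    beta: float = 0.01
    iters: int = 200
    restarts: int = 3
    min_count: int = 1
    df_threshold: float = 0.30
    drop_zero_days: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides take precedence."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _write_posts_tokens_jsonl(posts, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "post_id": p.post_id,
                        "date": p.date.isoformat(),
                        "region": p.region,
                        "text": p.raw_text,
                        "tokens": list(p.tokens),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("topics", _stage_topics),
        ("meteo", _stage_meteo),
        ("attention", _stage_attention),
        ("perceive", _stage_perceive),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            rows = fn(config, out, state)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        log.info("stage %s: %d row(s) in %.2fs", name, rows, elapsed)
        manifest["stages"].append({"stage": name, "rows": rows, "seconds": round(elapsed, 3)})

    manifest["post_conservation"] = state["conservation"]
    manifest["spearman_attention_tmax"] = state.get("spearman")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> int:
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    if not config.simulate:
        for key in ("posts_path", "gsod_path", "regions_path", "station_map_path"):
            if getattr(config, key) is None:
                raise ValueError(f"simulate is off but {key} is not set")
        state["paths"] = {
            "posts": config.posts_path,
            "gsod": config.gsod_path,
            "regions": config.regions_path,
            "station_map": config.station_map_path,
        }
        return 0
    world = synthetic.default_world(seed=config.seed, n_regions=config.n_regions)
    stations = synthetic.simulate_temperatures(world)
    temps = meteo.region_daily_tmax(stations, synthetic.station_region_map(world))
    posts = synthetic.simulate_posts(world, temps)
    paths = {
        "posts": str(inputs / "posts.jsonl"),
        "gsod": str(inputs / "gsod.csv"),
        "regions": str(inputs / "regions.csv"),
        "station_map": str(inputs / "station_map.csv"),
    }
    synthetic.write_posts_jsonl(posts, paths["posts"])
    meteo.write_gsod(stations, paths["gsod"])
    synthetic.write_regions_csv(world, paths["regions"])
    synthetic.write_station_map_csv(world, paths["station_map"])
    state["paths"] = paths
    state["window"] = (world.date_start, world.date_end)
    return len(posts)


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> int:
    posts = synthetic.read_posts_jsonl(state["paths"]["posts"])
    n_in = len(posts)
    keywords = config.keywords
    if keywords is None:
        keywords = list(synthetic.SYNTHETIC_KEYWORDS) if config.simulate else sorted(
            text_prep.DEFAULT_KEYWORDS
        )
    stopwords = None
    if config.stopword_paths:
        lists = [text_prep.read_stopword_list(p) for p in config.stopword_paths]
        stopwords = text_prep.merge_stopwords(
            lists, provenance=[str(p) for p in config.stopword_paths]
        )

    cleaned = [
        dataclasses.replace(p, raw_text=text_prep.clean_text(p.raw_text))
        for p in posts
    ]
    retained = [p for p in cleaned if text_prep.filter_heat_related(p, keywords)]
    n_filtered = n_in - len(retained)
    tokenized = [
        text_prep.tokenize(p, text_prep.whitespace_segmenter, stopwords)
        for p in retained
    ]
    kept = [p for p in tokenized if p.tokens]
    n_empty = len(tokenized) - len(kept)
    state["posts"] = kept
    state["conservation"] = {
        "posts_in": n_in,
        "retained": len(kept),
        "dropped_by_filter": n_filtered,
        "dropped_empty": n_empty,
    }
    _write_posts_tokens_jsonl(kept, out / "posts_tokenized.jsonl")
    return len(kept)


def _stage_topics(config: RunConfig, out: Path, state: dict) -> int:
    corpus = lda.build_corpus(state["posts"], min_count=config.min_count)
    model = lda.fit_lda(
        corpus, K=config.K, alpha=config.alpha, beta=config.beta,
        iters=config.iters, seed=config.seed, restarts=config.restarts,
    )
    shares = lda.topic_shares(model)
    shares.to_csv(out / "topic_shares.csv", index=False, float_format="%.1f")
    regional = lda.regional_topic_distribution(model, corpus)
    regional.to_csv(out / "regional_topics.csv", index=False, float_format="%.1f")
    rows = [
        {"topic": k, "rank": r + 1, "token": tok}
        for k in range(model.K)
        for r, tok in enumerate(lda.top_words(model, k, 10, corpus))
    ]
    pd.DataFrame(rows).to_csv(out / "topic_top_words.csv", index=False)
    state["model"] = model
    return len(corpus.docs)


def _stage_meteo(config: RunConfig, out: Path, state: dict) -> int:
    stations = meteo.read_gsod(state["paths"]["gsod"])
    smap = pd.read_csv(state["paths"]["station_map"], dtype=str)
    station_map = dict(zip(smap["station"], smap["region"]))
    temps = meteo.region_daily_tmax(stations, station_map)
    pd.DataFrame(
        [
            (t.region, t.date.isoformat(), t.tmax_c, t.n_stations)
            for t in temps
        ],
        columns=["region", "date", "tmax_c", "n_stations"],
    ).to_csv(out / "region_daily_tmax.csv", index=False, float_format="%.6f")
    meteo.monthly_mean_tmax(temps).to_csv(
        out / "region_monthly_tmax.csv", index=False, float_format="%.6f"
    )
    state["temps"] = temps
    return len(temps)


def _stage_attention(config: RunConfig, out: Path, state: dict) -> int:
    regions_df = pd.read_csv(state["paths"]["regions"])
    gdp = dict(zip(regions_df["region"].astype(str), regions_df["gdp_wan_yuan"].astype(float)))
    window = state.get("window")
    if config.date_start and config.date_end:
        window = (dt.date.fromisoformat(config.date_start), dt.date.fromisoformat(config.date_end))
    daily = attn.daily_attention(
        state["posts"], gdp,
        date_start=window[0] if window else None,
        date_end=window[1] if window else None,
        drop_zero_days=config.drop_zero_days,
    )
    pd.DataFrame(
        [
            (r.region, r.date.isoformat(), r.n_posts, r.gdp, r.index)
            for r in daily
        ],
        columns=["region", "date", "n_posts", "gdp_wan_yuan", "index"],
    ).to_csv(out / "attention_index.csv", index=False, float_format="%.6f")

    period = attn.period_attention(state["posts"], gdp)
    pd.DataFrame(
        [(r.region, r.n_posts, r.gdp, r.index) for r in period],
        columns=["region", "n_posts", "gdp_wan_yuan", "index"],
    ).to_csv(out / "attention_period.csv", index=False, float_format="%.6f")

    # validation: period attention vs period-mean daily maximum temperature
    mean_tmax = (
        pd.DataFrame(
            [(t.region, t.tmax_c) for t in state["temps"]],
            columns=["region", "tmax_c"],
        )
        .groupby("region")["tmax_c"]
        .mean()
    )
    idx = {r.region: r.index for r in period}
    common = [r for r in sorted(idx) if r in mean_tmax.index]
    if len(common) >= 3:
        rho, p = attn.spearman_assoc(
            [mean_tmax[r] for r in common], [idx[r] for r in common]
        )
        state["spearman"] = {"rho": round(rho, 4), "p": p, "n": len(common)}
    state["daily_attention"] = daily
    return len(daily)


def _stage_perceive(config: RunConfig, out: Path, state: dict) -> int:
    obs = perception.build_observations(state["daily_attention"], state["temps"])
    fits = perception.fit_all_regions(obs, posts=state["posts"], temps=state["temps"])
    rows = []
    for f in fits:
        rows.append(
            {
                "region": f.region,
                "n_obs": f.n_obs,
                "a0": f.a0,
                "a1": f.a1,
                "a2": f.a2,
                "r2": f.r2,
                "mean_attention": f.mean_attention,
                "vertex_c": "" if f.vertex_c is None else round(f.vertex_c, 4),
                "tolerance_c": "" if f.tolerance_c is None else round(f.tolerance_c, 4),
                "sensitivity": f.sensitivity,
                "threshold_c": "" if f.threshold_c is None else round(f.threshold_c, 4),
                "flags": ";".join(f.flags),
            }
        )
    pd.DataFrame(rows).to_csv(out / "perception_fits.csv", index=False, float_format="%.6f")
    state["fits"] = fits
    return len(fits)
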