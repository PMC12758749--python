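# heatlens

**heatlens** turns geo-dated short-text posts and daily station temperatures
into measures of how the public perceives summer heat. It is aimed at
infodemiology / digital health surveillance work: given a corpus of
heat-related posts (one record per post: id, date, region, text), daily
maximum temperatures in the GSOD daily-summary dialect, and per-region
per-capita GDP, it produces per-region topic distributions, heat attention
indices, and quadratic heat-perception statistics — heat tolerance, heat
sensitivity, and the heat perception threshold.

Because real microblog corpora cannot be redistributed, the package ships a
first-class synthetic-data generator that emits worlds with known
generative structure (seasonal AR(1) station temperatures, Poisson post
volumes following a quadratic attention–temperature law, post texts from a
known LDA model), so the whole pipeline is testable end to end with no
download.

## The model

**Topics.** Latent Dirichlet allocation fitted by collapsed Gibbs sampling:
each document mixes K topics (θ_d ~ Dir(α)), each topic is a word
distribution (φ_k ~ Dir(β)); topic assignments are resampled from

&nbsp;&nbsp;&nbsp;&nbsp;p(z = k | z₋, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + V·β)

with α = 0.1, β = 0.01 by default (sparse, interpretable topics for short
noisy text). Each post is assigned its dominant topic; shares and
region×topic tables follow by counting.

**Attention.** For region *i* with per-capita GDP gdp_i (ten-thousand-yuan
units), the heat attention index is N = N_i / gdp_i at period resolution
and T = N_ij / gdp_i per day — post volume normalised for economic
development, validated against temperature by Spearman rank correlation.

**Perception.** Daily attention is regressed on daily maximum temperature ω:

&nbsp;&nbsp;&nbsp;&nbsp;T = a0 + a1·ω + a2·ω² + ε

From a convex fit (a2 > 0): the **vertex** −a1/(2a2) is the comfort point
where attention stops falling; **heat sensitivity** is a2 itself; **heat
tolerance** is the larger root of a2ω² + a1ω + (a0 − M) = 0, the
temperature above which attention exceeds the region's mean level M; the
**heat perception threshold** is the post-weighted mean daily maximum over
the region's posting days.

## Worked example

`python examples/05_heat_perception.py` simulates a 10-region, 62-day
peak-summer world whose generative comfort points span 24–34 °C, runs
posts → attention → perception, and prints:

```
75245 posts over 62 days, 10 regional fits
region  true-vertex  vertex   tolerance  sensitivity  threshold
R00       24.00    24.07      27.91        0.096      28.40
R01       25.11    23.78      27.58        0.122      27.99
...
R08       32.89    34.12      40.63        0.687      27.20
R09       34.00    34.22      40.94        0.973      27.25
```

Recovered vertices track the generative ones, and both tolerance and
sensitivity increase along the generative gradient — the rank correlations
are 1.00 (vertex vs tolerance) and 0.99 (curvature vs sensitivity).
`python examples/03_topic_model.py` does the same for topics: a corpus
generated with dominant-topic shares (26.0, 52.6, 11.4, 10.0)% is recovered
as (26.1, 52.4, 11.4, 10.1)% after Hungarian label matching.

The other examples cover simulation (`01`), text cleaning and keyword
filtering (`02`), the attention index and its Spearman validation (`04`),
and the one-command pipeline (`06`).

## Command line

```bash
heatlens run --seed 1 --out run_dir          # full pipeline on a synthetic world
heatlens simulate --seed 1 --out inputs      # just write input files
heatlens preprocess --posts inputs/posts.jsonl --out tokens.jsonl
heatlens topics --posts tokens.jsonl --k 4 --seed 1 --out tables
heatlens meteo --gsod inputs/gsod.csv --station-map inputs/station_map.csv --out tables
heatlens attention --posts tokens.jsonl --regions inputs/regions.csv --daily --out attn.csv
heatlens perceive --attention attn.csv --temps tables/region_daily_tmax.csv --out fits.csv
```

`heatlens run` accepts a flat YAML config (`--config run.yaml`); CLI flags
override file values. Every run writes a manifest with the config hash,
seed, per-stage row counts and the post-conservation balance; identical
config and seed give byte-identical tables.

## Layout

- `src/heatlens/` — the library: `synthetic` (seeded worlds), `text_prep`
  (cleaning/filtering/tokenizing), `lda` (collapsed Gibbs LDA), `meteo`
  (GSOD parsing and aggregation), `attention`, `perception`, `pipeline`,
  `cli`.
- `examples/` — one short narrative script per capability.
- `tests/` — pytest suite with brute-force oracles in `tests/oracles.py`.
- `docs/methods.md` — the model, its assumptions, parameter choices and
  known limitations.
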